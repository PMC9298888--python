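"""Synthetic sociometric trust surveys with planted statistical structure.

The generator emulates the study conditions a whole-network trust survey
produces: a bounded roster (default 57 members, of whom ~75% respond, plus
a couple of nominated outside organizations for a 59-node universe), a
right-tailed nomination-count distribution centred near five names, 5-point
Likert trust ratings whose seven dimensions carry a planted inter-dimension
correlation, extra agreement on mutually-nominated dyads (planting edge
reciprocity), and optional isolated newcomer clusters that only nominate
each other.

Response model
--------------
Each directed dyad (respondent, alter) receives a latent 7-vector

    z_d = sqrt(1 - tc^2) * eps_d + tc * a(r, alter) + beta * mutual + mu

where ``eps`` is multivariate normal with correlation chosen so the *coded
responses* (-1..+1, after thresholding to the 5-point scale) recover the
planted correlation ``rho`` — the Gaussian-copula correlation is inflated
by the discretization attenuation factor ``1 / lambda^2`` with
``lambda = corr(Z, code(Z))`` computed from the Likert marginal.  ``a`` is
a symmetric standard-normal dyad affinity shared with the collaboration
rating (coupling ``tc``), ``beta`` boosts both directions of mutually
nominated dyads, and ``mu`` shifts the whole scale toward agreement.
Thresholds are the normal quantiles of the configured marginal Likert
distribution.

Ground truth (planted rho, mutual dyads, cluster assignments) is returned
with the data so recovery tests never re-estimate it from the sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .survey import MAX_NOMINATIONS, N_DIMENSIONS, Roster, SurveyRecord

#: coded values of the 5 Likert responses, strongly disagree .. strongly agree
_CODES = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])


def likert_attenuation(marginal_probs: Sequence[float]) -> float:
    """Correlation attenuation factor lambda = corr(Z, code(Z)) when a
    standard normal Z is cut at the quantiles of ``marginal_probs`` and the
    five bins are coded -1..+1.

    For jointly normal (X, Y) with correlation r, the coded responses
    correlate approximately lambda^2 * r; the generator divides by this to
    plant correlations on the coded scale.
    """
    p = np.asarray(marginal_probs, float)
    if p.shape != (5,) or not np.isclose(p.sum(), 1.0) or (p <= 0).any():
        raise ValueError("marginal_probs must be 5 positive values summing to 1")
    cuts = norm.ppf(np.cumsum(p)[:4])
    pdf = np.concatenate([[0.0], norm.pdf(cuts), [0.0]])
    # E[Z * code(Z)] = sum_k v_k (phi(c_{k-1}) - phi(c_k))
    ez_code = float(np.sum(_CODES * (pdf[:-1] - pdf[1:])))
    mean = float(np.sum(_CODES * p))
    var = float(np.sum(_CODES**2 * p) - mean**2)
    return ez_code / np.sqrt(var)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale defaults for the synthetic survey.

    ``rho`` is the planted correlation between the *coded responses* of any
    two trust dimensions (scalar for an equicorrelated matrix, or a full
    7x7 symmetric PSD matrix with unit diagonal).  ``reciprocity_boost``
    (beta) raises the latent agreement on both directions of mutually
    nominated dyads; note that a nonzero beta adds a shared component
    across dimensions and therefore inflates observed inter-dimension
    correlations beyond ``rho``.
    """

    n_roster: int = 57
    n_external: int = 2          # nominated organizations outside the roster
    response_rate: float = 0.75
    #: P(nomination count = 1..7); mode at five names, bounded at seven
    nomination_probs: tuple[float, ...] = (0.02, 0.04, 0.08, 0.16, 0.30, 0.22, 0.18)
    #: marginal Likert distribution, strongly disagree .. strongly agree
    marginal_probs: tuple[float, ...] = (0.10, 0.15, 0.25, 0.30, 0.20)
    rho: float | Sequence[Sequence[float]] = 0.55
    reciprocity_boost: float = 0.5
    agreement_shift: float = 0.0   # mu, additive latent shift toward agreement
    affinity_scale: float = 1.0    # concentration of nomination preferences
    trust_coupling: float = 0.3    # tc, dyad affinity -> trust latent
    collab_coupling: float = 0.8   # dyad affinity -> collaboration latent
    #: marginal distribution of collaboration intensity 0..5 for named alters
    collab_probs: tuple[float, ...] = (0.04, 0.10, 0.16, 0.22, 0.24, 0.24)
    newcomer_clusters: tuple[int, ...] = ()
    cross_cluster_affinity: float = 0.0
    seed: int | None = None

    def rho_matrix(self) -> np.ndarray:
        if np.isscalar(self.rho):
            r = np.full((N_DIMENSIONS, N_DIMENSIONS), float(self.rho))
            np.fill_diagonal(r, 1.0)
            return r
        r = np.asarray(self.rho, float)
        if r.shape != (N_DIMENSIONS, N_DIMENSIONS) or not np.allclose(r, r.T):
            raise ValueError("rho must be a symmetric 7x7 matrix")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("rho must have a unit diagonal")
        return r

    def validate(self) -> None:
        if not 0 < self.response_rate <= 1:
            raise ValueError("response_rate must be in (0, 1]")
        if len(self.nomination_probs) != MAX_NOMINATIONS:
            raise ValueError(f"nomination_probs must have {MAX_NOMINATIONS} entries")
        if sum(self.newcomer_clusters) > self.n_roster:
            raise ValueError("newcomer cluster sizes exceed the roster")
        if any(s < 2 for s in self.newcomer_clusters):
            raise ValueError("a newcomer cluster needs >= 2 members to interact")
        if not 0 <= self.trust_coupling < 1:
            raise ValueError("trust_coupling must be in [0, 1)")
        self.rho_matrix()


def _latent_correlation(cfg: GeneratorConfig) -> np.ndarray:
    """Correlation for the dimension-specific component ``eps`` such that
    the total coded-response correlation is the planted rho."""
    lam2 = likert_attenuation(cfg.marginal_probs) ** 2
    tc2 = cfg.trust_coupling**2
    target_latent = np.clip(cfg.rho_matrix() / lam2, -0.99, 0.99)
    np.fill_diagonal(target_latent, 1.0)
    eps_corr = (target_latent - tc2) / (1.0 - tc2)
    np.fill_diagonal(eps_corr, 1.0)
    # guard PSD: nudge toward identity until a Cholesky factor exists
    for shrink in np.linspace(0.0, 0.5, 11):
        m = (1 - shrink) * eps_corr + shrink * np.eye(N_DIMENSIONS)
        try:
            np.linalg.cholesky(m)
            return m
        except np.linalg.LinAlgError:
            continue
    raise ValueError("planted rho is too far from positive semi-definite")


def _discretize(z: np.ndarray, probs: Sequence[float], lowest: int) -> np.ndarray:
    cuts = norm.ppf(np.cumsum(np.asarray(probs, float))[:-1])
    return lowest + np.searchsorted(cuts, z)


def generate_survey(
    cfg: GeneratorConfig, seed: int | None = None
) -> tuple[Roster, list[SurveyRecord], dict]:
    """Draw one synthetic survey.

    Returns ``(roster, records, ground_truth)`` where ``ground_truth`` holds
    the planted coded-scale correlation matrix, the set of mutually
    nominated dyads, the cluster assignment of every node, and the
    respondent list.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    width = len(str(cfg.n_roster))
    roster_ids = [f"M{i + 1:0{width}d}" for i in range(cfg.n_roster)]
    external_ids = [f"X{i + 1:02d}" for i in range(cfg.n_external)]
    ids = roster_ids + external_ids
    n = len(ids)

    # cluster 0 is the main partnership; newcomer clusters are carved from
    # the roster tail; external organizations sit in the main cluster
    cluster = np.zeros(n, dtype=int)
    pos = cfg.n_roster
    for c, size in enumerate(cfg.newcomer_clusters, start=1):
        cluster[pos - size:pos] = c
        pos -= size

    # symmetric dyad affinity, shared by nominations, trust and collaboration
    a = rng.standard_normal((n, n))
    affinity = (a + a.T) / np.sqrt(2.0)
    np.fill_diagonal(affinity, -np.inf)

    responded = rng.random(cfg.n_roster) < cfg.response_rate
    respondents = [i for i in range(cfg.n_roster) if responded[i]]

    # Nominations.  The reciprocity boost beta acts here as well as on the
    # ratings: respondents (processed in random order) up-weight candidates
    # who already nominated them by exp(beta), and afterwards respondents
    # with spare capacity reciprocate incoming nominations with probability
    # 1 - exp(-beta).  Both effects vanish at beta = 0.
    beta = cfg.reciprocity_boost
    nominations: dict[int, list[int]] = {}
    for r in rng.permutation(respondents):
        r = int(r)
        pref = np.exp(cfg.affinity_scale * affinity[r])  # exp(-inf) = 0 on self
        same = cluster == cluster[r]
        pref = np.where(same, pref, pref * cfg.cross_cluster_affinity)
        pref[r] = 0.0
        nominated_me = [a_ for a_, alters in nominations.items() if r in alters]
        pref[nominated_me] *= np.exp(beta)
        eligible = int(np.count_nonzero(pref))
        if eligible == 0:
            nominations[r] = []
            continue
        k = 1 + int(rng.choice(MAX_NOMINATIONS, p=cfg.nomination_probs))
        k = min(k, eligible)
        p = pref / pref.sum()
        nominations[r] = list(int(x) for x in rng.choice(n, size=k, replace=False, p=p))
    if beta > 0:
        p_rec = 1.0 - np.exp(-beta)
        for r in respondents:
            for a_ in list(nominations[r]):
                if (
                    a_ in nominations
                    and r not in nominations[a_]
                    and len(nominations[a_]) < MAX_NOMINATIONS
                    and rng.random() < p_rec
                ):
                    nominations[a_].append(r)

    mutual = {
        (r, a_)
        for r, alters in nominations.items()
        for a_ in alters
        if a_ in nominations and r in nominations[a_]
    }

    chol = np.linalg.cholesky(_latent_correlation(cfg))
    tc = cfg.trust_coupling
    records = []
    for r in respondents:
        alters = nominations[r]
        if not alters:
            records.append(SurveyRecord(ids[r], (), (), ()))
            continue
        eps = rng.standard_normal((len(alters), N_DIMENSIONS)) @ chol.T
        aff = affinity[r, alters][:, None]
        boost = np.array([(r, x) in mutual for x in alters], float)[:, None]
        z = (
            np.sqrt(1 - tc**2) * eps
            + tc * aff
            + cfg.reciprocity_boost * boost
            + cfg.agreement_shift
        )
        ratings = _discretize(z, cfg.marginal_probs, lowest=1)
        cz = (
            cfg.collab_coupling * aff[:, 0]
            + np.sqrt(1 - cfg.collab_coupling**2) * rng.standard_normal(len(alters))
        )
        collab = _discretize(cz, cfg.collab_probs, lowest=0)
        records.append(
            SurveyRecord(
                respondent_id=ids[r],
                alters=tuple(ids[x] for x in alters),
                collaboration=tuple(int(c) for c in collab),
                trust=tuple(tuple(int(t) for t in row) for row in ratings),
            )
        )

    ground_truth = {
        "rho": cfg.rho_matrix(),
        "mutual_dyads": {(ids[r], ids[a_]) for r, a_ in mutual},
        "clusters": {ids[i]: int(cluster[i]) for i in range(n)},
        "respondents": [ids[r] for r in respondents],
        "universe": ids,
    }
    return Roster(frozenset(ids)), records, ground_truth


def fixture_suite() -> dict[str, tuple[Roster, list[SurveyRecord]]]:
    """Deterministic micro-datasets with known measure values, used across
    the test suite.

    * ``mutual_dyad`` — A and B nominate each other with full agreement:
      reciprocity 1.0 on every rated dimension.
    * ``in_star`` — four spokes each nominate hub H with strong agreement:
      weighted in-degree centralization 1.0.
    * ``path`` — A trusts B, B trusts C: a single geodesic through B.
    * ``table_shape`` — study-scale synthetic survey (59-node universe).
    """
    all5 = (5,) * N_DIMENSIONS

    def rec(resp, alters, collab, trust):
        return SurveyRecord(resp, tuple(alters), tuple(collab), tuple(trust))

    mutual = (
        Roster(frozenset({"A", "B", "C"})),
        [
            rec("A", ["B"], [5], [all5]),
            rec("B", ["A"], [5], [all5]),
        ],
    )
    star = (
        Roster(frozenset({"H", "S1", "S2", "S3", "S4"})),
        [rec(s, ["H"], [5], [all5]) for s in ("S1", "S2", "S3", "S4")],
    )
    path = (
        Roster(frozenset({"A", "B", "C"})),
        [
            rec("A", ["B"], [3], [all5]),
            rec("B", ["C"], [3], [all5]),
        ],
    )
    roster, records, _ = generate_survey(GeneratorConfig(seed=20210501))
    return {
        "mutual_dyad": mutual,
        "in_star": star,
        "path": path,
        "table_shape": (roster, records),
    }
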
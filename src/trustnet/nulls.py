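"""Null models and 95% quantile envelopes for network statistics.

Two null hypotheses are simulated and compared against the observed layer:

* **random** — participants fill the survey out at random: each simulated
  respondent draws a nomination count uniformly on {0..max}, picks alters
  uniformly without replacement, and draws every ordinal rating uniformly.
  Networks are then built with the same coding rules as the observed data.
* **preferential** — trust attaches preferentially: a directed growth
  process in which each arriving node sends its edges to existing nodes
  with probability proportional to (current in-degree + smoothing), the
  per-arrival edge budget is set to match the observed layer's edge count,
  and weights are resampled from the observed layer's empirical weight
  distribution.

For each model the same network-level battery is computed over many
iterations; the 2.5% and 97.5% empirical quantiles form the envelope, and
an observed value outside it is inconsistent with that model at the 95%
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .layers import TrustLayer, build_all_layers
from .metrics import MeasureTable, measure_table
from .survey import MAX_NOMINATIONS, Roster, SurveyRecord

MODELS = ("random", "preferential")


@dataclass(frozen=True)
class NullConfig:
    """Settings for null-model simulation.

    ``n_nodes``/``n_respondents`` default to the study scale: a 59-node
    universe of which 43 members completed the survey.  ``smoothing`` is the
    additive constant in the preferential target probability
    (in-degree + smoothing), keeping in-degree-0 nodes reachable.
    """

    iterations: int = 1000
    seed: int | None = None
    n_nodes: int = 59
    n_respondents: int = 43
    max_nominations: int = MAX_NOMINATIONS
    smoothing: float = 1.0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.max_nominations < 0:
            raise ValueError("max_nominations must be >= 0")
        if not 0 < self.n_respondents <= self.n_nodes:
            raise ValueError("need 0 < n_respondents <= n_nodes")


@dataclass(frozen=True)
class EnvelopeResult:
    """Observed value of one measure against one null model's 95% envelope."""

    layer: str
    measure: str
    model: str
    observed: float | None
    null_mean: float | None
    q_lo: float | None
    q_hi: float | None
    outside: bool | None
    n_defined: int = 0
    n_dropped: int = 0


def _node_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"N{i:0{width}d}" for i in range(n)]


def simulate_random_survey(
    cfg: NullConfig, rng: np.random.Generator
) -> tuple[Roster, list[SurveyRecord]]:
    """Simulate one survey under the random-completion null.

    Respondent set drawn uniformly from the universe; each respondent's
    nomination count is uniform on {0..max_nominations}, alters uniform
    without replacement, trust ratings uniform on 1..5 and collaboration
    uniform on 0..5.
    """
    if cfg.n_nodes < cfg.max_nominations + 1:
        raise ValueError(
            f"universe of {cfg.n_nodes} cannot support "
            f"{cfg.max_nominations} distinct nominations"
        )
    ids = _node_ids(cfg.n_nodes)
    respondents = rng.choice(cfg.n_nodes, size=cfg.n_respondents, replace=False)
    records = []
    for ri in sorted(respondents):
        k = int(rng.integers(0, cfg.max_nominations + 1))
        candidates = [i for i in range(cfg.n_nodes) if i != ri]
        alters = rng.choice(candidates, size=k, replace=False) if k else []
        trust = tuple(
            tuple(int(t) for t in rng.integers(1, 6, size=7)) for _ in range(k)
        )
        collab = tuple(int(c) for c in rng.integers(0, 6, size=k))
        records.append(
            SurveyRecord(
                respondent_id=ids[ri],
                alters=tuple(ids[a] for a in alters),
                collaboration=collab,
                trust=trust,
            )
        )
    return Roster(frozenset(ids)), records


def preferential_targets(
    in_degrees: np.ndarray, m: int, smoothing: float, rng: np.random.Generator
) -> list[int]:
    """Choose ``m`` distinct targets with probability proportional to
    (in-degree + smoothing), renormalizing after each choice."""
    weights = in_degrees.astype(float) + smoothing
    chosen: list[int] = []
    for _ in range(m):
        p = weights / weights.sum()
        t = int(rng.choice(len(weights), p=p))
        chosen.append(t)
        weights[t] = 0.0
    return chosen


def simulate_preferential(
    cfg: NullConfig,
    target_edges: int,
    rng: np.random.Generator,
    weight_pool: tuple[float, ...] = (1.0,),
    label: str = "preferential",
    weight_cap: float = 1.0,
) -> TrustLayer:
    """Grow one directed preferential-attachment network of ``cfg.n_nodes``
    nodes and (exactly) ``target_edges`` edges.

    Nodes arrive in random order; arrival ``i`` may send up to ``i`` edges
    (one per distinct earlier node).  The total budget is spread uniformly
    over arrivals, overflow rolling forward, so any feasible edge count
    0 <= E <= n(n-1)/2 is met exactly.  Weights are drawn i.i.d. from
    ``weight_pool`` (the observed layer's empirical weights).
    """
    n = cfg.n_nodes
    if not 0 <= target_edges <= n * (n - 1) // 2:
        raise ValueError(
            f"edge budget {target_edges} infeasible for {n}-node growth "
            f"(max {n * (n - 1) // 2})"
        )
    ids = _node_ids(n)
    arrival = rng.permutation(n)
    # spread the budget over the n-1 arriving nodes, respecting the cap of
    # i available targets at arrival i; overflow rolls to later arrivals
    quota = [0] * n
    base, extra = divmod(target_edges, max(n - 1, 1))
    lucky = set(rng.choice(np.arange(1, n), size=extra, replace=False)) if extra else set()
    carry = 0
    for i in range(1, n):
        want = base + (1 if i in lucky else 0) + carry
        quota[i] = min(want, i)
        carry = want - quota[i]
    for i in range(n - 1, 0, -1):  # any remaining overflow fills from the tail
        if carry <= 0:
            break
        room = i - quota[i]
        add = min(room, carry)
        quota[i] += add
        carry -= add

    g = nx.DiGraph()
    g.add_nodes_from(sorted(ids))
    indeg = np.zeros(n)
    existing: list[int] = []
    for i in range(n):
        node = arrival[i]
        if quota[i] > 0:
            picks = preferential_targets(
                indeg[existing], quota[i], cfg.smoothing, rng
            )
            for p in picks:
                tgt = existing[p]
                w = float(weight_pool[int(rng.integers(len(weight_pool)))])
                g.add_edge(ids[node], ids[tgt], weight=w)
                indeg[tgt] += 1
        existing.append(node)
    return TrustLayer(label=label, graph=g, weight_cap=weight_cap)


def _simulate_layer(
    observed: TrustLayer, model: str, cfg: NullConfig, rng: np.random.Generator
) -> TrustLayer:
    if model == "random":
        _, records = simulate_random_survey(cfg, rng)
        layers = build_all_layers(records, universe=_node_ids(cfg.n_nodes))
        if observed.label in layers:
            return layers[observed.label]
        # non-standard label: reuse the first-dimension coding rules
        return layers["trust_1"]
    if model == "preferential":
        pool = tuple(observed.weights()) or (1.0,)
        return simulate_preferential(
            cfg,
            observed.n_edges,
            rng,
            weight_pool=pool,
            label=observed.label,
            weight_cap=observed.weight_cap,
        )
    raise ValueError(f"unknown null model {model!r}; expected one of {MODELS}")


def envelope(
    layer_observed: TrustLayer,
    model: str,
    cfg: NullConfig,
) -> list[EnvelopeResult]:
    """Simulate ``cfg.iterations`` null networks, measure each, and compare
    the observed layer's statistics to the 2.5/97.5% empirical quantiles.

    Iterations use independent child streams spawned from ``cfg.seed``, so
    results are reproducible and order-independent.  Undefined simulated
    values are dropped from the quantile computation (their count is
    reported in ``n_dropped``); a measure undefined in *every* iteration
    yields an undefined envelope.
    """
    if cfg.iterations < 40:
        raise ValueError(
            "need >= 40 iterations to estimate 2.5/97.5% quantiles; "
            f"got {cfg.iterations}"
        )
    if model not in MODELS:
        raise ValueError(f"unknown null model {model!r}; expected one of {MODELS}")
    cfg = replace(cfg, n_nodes=layer_observed.n_nodes)
    observed = measure_table(layer_observed).as_dict()
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.iterations)
    sims: dict[str, list[float]] = {m: [] for m in MeasureTable.measure_names()}
    dropped: dict[str, int] = {m: 0 for m in sims}
    for ss in streams:
        sim = _simulate_layer(layer_observed, model, cfg, np.random.default_rng(ss))
        for name, value in measure_table(sim).as_dict().items():
            if value is None or (isinstance(value, float) and math.isnan(value)):
                dropped[name] += 1
            else:
                sims[name].append(float(value))

    results = []
    for name in MeasureTable.measure_names():
        vals = sims[name]
        obs = observed[name]
        if not vals:
            results.append(
                EnvelopeResult(
                    layer=layer_observed.label, measure=name, model=model,
                    observed=obs, null_mean=None, q_lo=None, q_hi=None,
                    outside=None, n_defined=0, n_dropped=dropped[name],
                )
            )
            continue
        arr = np.asarray(vals)
        q_lo, q_hi = np.quantile(arr, [0.025, 0.975])  # type-7 interpolation
        outside = None if obs is None else bool(obs < q_lo or obs > q_hi)
        results.append(
            EnvelopeResult(
                layer=layer_observed.label, measure=name, model=model,
                observed=obs, null_mean=float(arr.mean()),
                q_lo=float(q_lo), q_hi=float(q_hi), outside=outside,
                n_defined=len(vals), n_dropped=dropped[name],
            )
        )
    return results
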
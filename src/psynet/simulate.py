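"""Two-group ordinal questionnaire simulator with planted networks.

Ground truth is a sparse partial-correlation network over the 19 items
(10 self-efficacy items S1-S10 on a 1-4 scale, 9 depression items D1-D9 on
a 0-3 scale).  Ordinal responses arise from a latent-Gaussian threshold
model: each participant draws a multivariate-normal latent vector whose
correlation structure is implied by the planted network, and each item's
latent value is cut at ordered thresholds into category codes.

Group differences are planted as edge edits (strengthen / weaken / add /
remove, the taxonomy of the study's change table) applied to the depressed
group's network, plus an optional exact global-strength gap.  Default
parameter values emulate the study design: a control group of 3,094 and a
depressed group of 560 adolescents, Table-3-style edge edits inside the
self-efficacy block, and a planted global-strength deficit of 0.25 in the
depressed group.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from ._utils import rng_for
from .errors import ConstructionError, ParameterError
from .ggm import precision_to_pcor

log = logging.getLogger(__name__)

GSES_ITEMS = [f"S{i}" for i in range(1, 11)]
PHQ9_ITEMS = [f"D{i}" for i in range(1, 10)]
STUDY_ITEMS = GSES_ITEMS + PHQ9_ITEMS

PD_TOL = 1e-8
PD_SHRINK = 0.95
PD_MAX_ITER = 100


def _study_communities() -> dict[str, str]:
    comm = {s: "self-efficacy" for s in GSES_ITEMS}
    comm.update({d: "depression" for d in PHQ9_ITEMS})
    return comm


@dataclass
class TrueNetwork:
    """Planted ground-truth partial-correlation structure."""

    labels: list[str]
    pcor: np.ndarray
    communities: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.pcor = np.asarray(self.pcor, dtype=float)
        p = len(self.labels)
        if self.pcor.shape != (p, p):
            raise ConstructionError("pcor shape must match labels")
        if not np.allclose(self.pcor, self.pcor.T, atol=1e-12):
            raise ConstructionError("pcor must be symmetric")
        if np.any(np.diag(self.pcor) != 0.0):
            raise ConstructionError("pcor diagonal must be zero")
        if np.any(np.abs(self.pcor) >= 1.0):
            raise ConstructionError("|partial correlation| must be < 1")
        if not self.communities:
            self.communities = {lab: "all" for lab in self.labels}

    @property
    def p(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def precision(self) -> np.ndarray:
        K = -self.pcor.copy()
        np.fill_diagonal(K, 1.0)
        return K

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.precision()).min())

    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.pcor, 1)))

    def density(self) -> float:
        possible = self.p * (self.p - 1) // 2
        return self.edge_count() / possible if possible else 0.0

    def global_strength(self) -> float:
        return float(np.abs(np.triu(self.pcor, 1)).sum())

    def copy(self) -> "TrueNetwork":
        return TrueNetwork(list(self.labels), self.pcor.copy(), dict(self.communities))


@dataclass
class EdgeEdit:
    """One planted group difference on a node pair.

    ``weight`` is the target partial correlation for strengthen / weaken /
    add / set; ``remove`` ignores it.
    """

    i: str
    j: str
    action: str  # strengthen | weaken | add | remove | set
    weight: float | None = None

    def __post_init__(self):
        if self.action not in {"strengthen", "weaken", "add", "remove", "set"}:
            raise ParameterError(f"unknown edit action: {self.action}")
        if self.action != "remove" and self.weight is None:
            raise ParameterError(f"action {self.action!r} needs a target weight")


def _repair_pd(pcor: np.ndarray, protected: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Shrink unprotected off-diagonals until the implied precision is PD.

    Returns the repaired matrix and the number of shrink iterations; raises
    if the protected entries alone are infeasible.
    """
    P = pcor.copy()
    if protected is None:
        protected = np.zeros_like(P, dtype=bool)
    for it in range(PD_MAX_ITER + 1):
        K = -P
        np.fill_diagonal(K, 1.0)
        if np.linalg.eigvalsh(K).min() > PD_TOL:
            return P, it
        free = ~protected
        np.fill_diagonal(free, False)
        if not free.any():
            break
        P[free] *= PD_SHRINK
    raise ConstructionError(
        "could not repair network to positive definiteness "
        f"within {PD_MAX_ITER} shrink iterations"
    )


def make_true_network(
    p: int | None = None,
    density: float = 0.3,
    weight_range: tuple[float, float] = (0.05, 0.30),
    communities: dict[str, str] | None = None,
    seed: int = 0,
    labels: list[str] | None = None,
    cross_weight_range: tuple[float, float] = (0.02, 0.10),
    cross_negative_prob: float = 0.8,
    cross_density: float | None = None,
) -> TrueNetwork:
    """Random sparse partial-correlation network.

    ``density`` governs within-community pairs: exactly ``floor(density *
    n_within_pairs)`` of them carry positive weights uniform in
    ``weight_range``.  Cross-community pairs use ``cross_density`` (default:
    same as ``density``) and ``cross_weight_range`` magnitudes, negative
    with probability ``cross_negative_prob`` (self-efficacy <-> depression
    links in the study are negative).  Without communities every pair counts
    as within, so the planted edge count is ``floor(density * p(p-1)/2)``.
    The matrix is repaired to positive definiteness by uniform shrinkage if
    needed; repairs are logged.
    """
    if communities is not None:
        labels = list(communities.keys()) if labels is None else list(labels)
    elif labels is None:
        if p is None:
            raise ParameterError("give p, labels or communities")
        labels = [f"V{i + 1}" for i in range(p)]
    p = len(labels)
    comm = communities or {lab: "all" for lab in labels}
    if cross_density is None:
        cross_density = density
    for d in (density, cross_density):
        if not (0.0 <= d <= 1.0):
            raise ParameterError("density must be in [0, 1]")
    lo, hi = weight_range
    if not (0.0 <= lo <= hi < 1.0):
        raise ParameterError("weight range must sit inside [0, 1)")

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(p, 1)
    same = np.array([comm[labels[i]] == comm[labels[j]] for i, j in zip(iu, ju)])
    P = np.zeros((p, p))
    for mask, dens in ((same, density), (~same, cross_density)):
        pairs = np.flatnonzero(mask)
        n_edges = int(np.floor(dens * len(pairs)))
        if not n_edges:
            continue
        chosen = rng.choice(pairs, size=n_edges, replace=False)
        for idx in chosen:
            i, j = int(iu[idx]), int(ju[idx])
            if same[idx]:
                w = rng.uniform(lo, hi)
            else:
                w = rng.uniform(*cross_weight_range)
                if rng.random() < cross_negative_prob:
                    w = -w
            P[i, j] = P[j, i] = w
    P, n_repair = _repair_pd(P)
    if n_repair:
        log.info("network repaired to PD in %d shrink iterations", n_repair)
    return TrueNetwork(labels, P, dict(comm))


def pcor_to_covariance(net: TrueNetwork) -> np.ndarray:
    """Unit-variance covariance (= correlation) implied by the network."""
    K = net.precision()
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ConstructionError("implied precision is not positive definite")
    Sigma = np.linalg.inv(K)
    d = 1.0 / np.sqrt(np.diag(Sigma))
    Sigma = Sigma * np.outer(d, d)
    np.fill_diagonal(Sigma, 1.0)
    return 0.5 * (Sigma + Sigma.T)


def apply_edge_edits(net: TrueNetwork, edits: list[EdgeEdit]) -> TrueNetwork:
    """Edited copy of a network; PD repair never touches the edited edges."""
    out = net.copy()
    protected = np.zeros_like(out.pcor, dtype=bool)
    for e in edits:
        i, j = out.index(e.i), out.index(e.j)
        if i == j:
            raise ParameterError("edit must reference two distinct nodes")
        cur = out.pcor[i, j]
        if e.action == "add" and cur != 0.0:
            raise ParameterError(f"add {e.i}-{e.j}: edge already present ({cur:g})")
        if e.action in {"strengthen", "weaken"} and cur == 0.0:
            raise ParameterError(f"{e.action} {e.i}-{e.j}: edge absent")
        if e.action == "strengthen" and abs(e.weight) <= abs(cur):
            raise ParameterError(f"strengthen {e.i}-{e.j}: |target| <= |current|")
        if e.action == "weaken" and abs(e.weight) >= abs(cur):
            raise ParameterError(f"weaken {e.i}-{e.j}: |target| >= |current|")
        val = 0.0 if e.action == "remove" else float(e.weight)
        out.pcor[i, j] = out.pcor[j, i] = val
        protected[i, j] = protected[j, i] = True
    out.pcor, n_repair = _repair_pd(out.pcor, protected)
    if n_repair:
        log.info("edited network repaired to PD in %d shrink iterations", n_repair)
    return out


def equal_probability_thresholds(n_categories: int) -> np.ndarray:
    """Latent cut-points giving equal category probabilities."""
    qs = np.arange(1, n_categories) / n_categories
    return stats.norm.ppf(qs)


def thresholds_from_cumprobs(cumprobs) -> np.ndarray:
    """Latent cut-points from cumulative category probabilities."""
    cp = np.asarray(cumprobs, dtype=float)
    if np.any(np.diff(cp) <= 0) or np.any(cp <= 0) or np.any(cp >= 1):
        raise ParameterError("cumulative probabilities must be strictly increasing in (0,1)")
    return stats.norm.ppf(cp)


@dataclass
class ItemResponseSample:
    """Simulated ordinal responses (thin container; scales_io re-validates)."""

    frame: "object"  # pandas DataFrame, columns = item labels

    def values_array(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def item_ids(self):
        return list(self.frame.columns)


def sample_likert(
    cov: np.ndarray,
    thresholds: list[np.ndarray],
    n: int,
    seed: int = 0,
    category_mins: list[int] | None = None,
    labels: list[str] | None = None,
):
    """Discretize latent multivariate-normal draws at per-item thresholds.

    ``thresholds[j]`` are the strictly increasing cut-points of item j; a
    latent value beyond the k-th cut-point raises the code by one, starting
    from ``category_mins[j]`` (default 1).  Deterministic given ``seed``.
    """
    import pandas as pd

    cov = np.asarray(cov, dtype=float)
    p = cov.shape[0]
    if len(thresholds) != p:
        raise ParameterError("one threshold vector per item required")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ConstructionError("covariance is not positive definite") from exc
    mins = category_mins if category_mins is not None else [1] * p
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p)) @ L.T
    codes = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        thr = np.asarray(thresholds[j], dtype=float)
        if thr.size and np.any(np.diff(thr) <= 0):
            raise ParameterError(f"thresholds for item {j} must be strictly increasing")
        codes[:, j] = mins[j] + np.searchsorted(thr, Z[:, j])
    cols = labels if labels is not None else [f"V{i + 1}" for i in range(p)]
    return ItemResponseSample(pd.DataFrame(codes, columns=cols))


def default_group_edits() -> list[EdgeEdit]:
    """Depressed-group edge changes planted by default.

    Mirrors the study's reported change profile inside the self-efficacy
    block: two strengthened edges, two weakened, one lost, three new links.
    Weights are the depressed-group values of that profile.
    """
    return [
        EdgeEdit("S1", "S3", "strengthen", 0.16),
        EdgeEdit("S2", "S3", "remove"),
        EdgeEdit("S2", "S4", "add", 0.07),
        EdgeEdit("S3", "S5", "weaken", 0.09),
        EdgeEdit("S3", "S6", "add", 0.11),
        EdgeEdit("S5", "S7", "strengthen", 0.28),
        EdgeEdit("S1", "S9", "weaken", 0.04),
        EdgeEdit("S2", "S9", "add", 0.08),
    ]


def default_base_edits() -> list[EdgeEdit]:
    """Control-group values pinned on the edges touched by the change profile."""
    return [
        EdgeEdit("S1", "S3", "set", 0.04),
        EdgeEdit("S2", "S3", "set", 0.16),
        EdgeEdit("S2", "S4", "set", 0.0),
        EdgeEdit("S3", "S5", "set", 0.22),
        EdgeEdit("S3", "S6", "set", 0.0),
        EdgeEdit("S5", "S7", "set", 0.13),
        EdgeEdit("S1", "S9", "set", 0.14),
        EdgeEdit("S2", "S9", "set", 0.0),
    ]


# Latent cut-points emulating the study's marginal score profile:
# control GSES item mean ~2.7 (total ~27), depressed ~2.2 (total ~22);
# control PHQ-9 item mean ~0.36 (total ~3.2), depressed ~1.5 (total ~14).
GSES_CUMPROBS = {"control": (0.13, 0.42, 0.77), "depressed": (0.30, 0.62, 0.89)}
PHQ9_CUMPROBS = {"control": (0.72, 0.93, 0.985), "depressed": (0.20, 0.50, 0.80)}

# Demographic profile of the study sample (per-group).
AGE_PROFILE = {"control": (15.17, 2.09), "depressed": (14.88, 1.83)}
FEMALE_RATE = {"control": 0.4270, "depressed": 0.5161}
EDUCATION_PROBS = {
    "control": (0.3862, 0.5743, 0.0394),
    "depressed": (0.4392, 0.5392, 0.0214),
}


@dataclass
class GeneratorConfig:
    """Study-design knobs for the two-group simulator.

    Defaults emulate the study conditions: 3,094 controls, 560 depressed,
    19 items in two communities.  The instrument blocks are dense with
    small positive weights (the reported self-efficacy networks had 37-39
    of 45 edges with mean weight ~0.1 and global strengths 4.3-4.6), the
    few cross-community bridges are weak and mostly negative, the default
    change profile alters eight self-efficacy edges, and the depressed
    group's self-efficacy block carries an exact 0.25 global-strength
    deficit.
    """

    n_control: int = 3094
    n_depressed: int = 560
    density: float = 0.85
    cross_density: float = 0.06
    weight_range: tuple[float, float] = (0.03, 0.20)
    cross_weight_range: tuple[float, float] = (0.02, 0.10)
    cross_negative_prob: float = 0.8
    base_edits: list[EdgeEdit] | None = None  # None -> default_base_edits()
    group_edits: list[EdgeEdit] | None = None  # None -> default_group_edits()
    strength_gap: float | None = 0.25
    gses_cumprobs: dict = field(default_factory=lambda: dict(GSES_CUMPROBS))
    phq9_cumprobs: dict = field(default_factory=lambda: dict(PHQ9_CUMPROBS))
    covariates: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("base_edits", "group_edits"):
            if d[key] is not None:
                d[key] = [asdict(e) if not isinstance(e, dict) else e for e in d[key]]
        return d


@dataclass
class SimulatedStudy:
    """Generator output: data per group plus the planted truth."""

    config: GeneratorConfig
    truth_control: TrueNetwork
    truth_depressed: TrueNetwork
    control: "object"  # DataFrame: items (+ covariates)
    depressed: "object"

    def combined_frame(self):
        """Single table with a planted group_true column, control rows first."""
        import pandas as pd

        a = self.control.copy()
        a["group_true"] = "control"
        b = self.depressed.copy()
        b["group_true"] = "depressed"
        return pd.concat([a, b], ignore_index=True)


def _apply_set_edits(net: TrueNetwork, edits: list[EdgeEdit]) -> TrueNetwork:
    """'set' edits bypass the add/strengthen/weaken preconditions."""
    out = net.copy()
    protected = np.zeros_like(out.pcor, dtype=bool)
    for e in edits:
        i, j = out.index(e.i), out.index(e.j)
        out.pcor[i, j] = out.pcor[j, i] = float(e.weight)
        protected[i, j] = protected[j, i] = True
    out.pcor, _ = _repair_pd(out.pcor, protected)
    return out


def _plant_strength_gap(
    base: TrueNetwork,
    edited: TrueNetwork,
    gap: float,
    pinned: list[EdgeEdit],
    scope: list[str] | None = None,
) -> TrueNetwork:
    """Scale the depressed network's un-pinned edges so the global-strength
    deficit relative to the base network equals ``gap`` exactly.

    ``scope`` restricts both the strength measurement and the rescaling to
    the subnetwork induced by those labels (the self-efficacy block in the
    default study design); edits must lie inside the scope, so the full-
    network strength difference equals the in-scope difference.
    """
    out = edited.copy()
    p = out.p
    in_scope = np.ones(p, dtype=bool)
    if scope is not None:
        in_scope = np.array([lab in set(scope) for lab in out.labels])
    scope_mask = np.outer(in_scope, in_scope)
    pin_mask = np.zeros_like(out.pcor, dtype=bool)
    for e in pinned:
        i, j = out.index(e.i), out.index(e.j)
        if not (in_scope[i] and in_scope[j]):
            raise ConstructionError("edited edges must lie inside the gap scope")
        pin_mask[i, j] = pin_mask[j, i] = True
    upper = np.triu(np.ones_like(out.pcor, dtype=bool), 1) & scope_mask
    base_scope = np.abs(base.pcor[np.triu(scope_mask, 1)]).sum()
    pinned_sum = np.abs(out.pcor[upper & pin_mask]).sum()
    free = upper & ~pin_mask
    free_sum = np.abs(out.pcor[free]).sum()
    target_free = base_scope - gap - pinned_sum
    if free_sum <= 0 or target_free < 0:
        raise ConstructionError("strength gap infeasible for this network")
    c = target_free / free_sum
    scale = (scope_mask & ~pin_mask)
    out.pcor[scale] = out.pcor[scale] * c
    np.fill_diagonal(out.pcor, 0.0)
    K = out.precision()
    if np.linalg.eigvalsh(K).min() <= PD_TOL:
        raise ConstructionError(
            f"strength-gap scaling (factor {c:.3f}) broke positive definiteness"
        )
    return out


def make_network_pair(
    communities: dict[str, str] | None = None,
    density: float = 0.3,
    weight_range: tuple[float, float] = (0.05, 0.30),
    cross_weight_range: tuple[float, float] = (0.02, 0.10),
    cross_negative_prob: float = 0.8,
    base_edits: list[EdgeEdit] | None = None,
    group_edits: list[EdgeEdit] | None = None,
    strength_gap: float | None = None,
    gap_scope: list[str] | None = None,
    seed: int = 0,
    **make_kwargs,
) -> tuple[TrueNetwork, TrueNetwork]:
    """(control, depressed) ground-truth pair.

    ``base_edits`` pin edge values on both networks (control-side values of
    the change profile); ``group_edits`` are then applied to the depressed
    copy; ``strength_gap`` finally rescales the depressed network's
    un-edited edges (inside ``gap_scope``, if given) so the control-minus-
    depressed global-strength difference is exact.
    """
    truth = make_true_network(
        communities=communities,
        density=density,
        weight_range=weight_range,
        cross_weight_range=cross_weight_range,
        cross_negative_prob=cross_negative_prob,
        seed=seed,
        **make_kwargs,
    )
    control = _apply_set_edits(truth, base_edits) if base_edits else truth
    depressed = apply_edge_edits(control, group_edits) if group_edits else control.copy()
    if strength_gap is not None:
        depressed = _plant_strength_gap(control, depressed, strength_gap,
                                        group_edits or [], scope=gap_scope)
    return control, depressed


def generate_two_group_study(config: GeneratorConfig | None = None) -> SimulatedStudy:
    """Simulate the full two-group study from a planted network pair."""
    import pandas as pd

    cfg = config or GeneratorConfig()
    base_edits = cfg.base_edits if cfg.base_edits is not None else default_base_edits()
    group_edits = cfg.group_edits if cfg.group_edits is not None else default_group_edits()

    truth_control, truth_depressed = make_network_pair(
        communities=_study_communities(),
        density=cfg.density,
        cross_density=cfg.cross_density,
        weight_range=cfg.weight_range,
        cross_weight_range=cfg.cross_weight_range,
        cross_negative_prob=cfg.cross_negative_prob,
        base_edits=base_edits,
        group_edits=group_edits,
        strength_gap=cfg.strength_gap,
        gap_scope=GSES_ITEMS,
        seed=int(rng_for(cfg.seed, "truth").integers(2**31)),
    )

    frames = {}
    for name, net, n in (
        ("control", truth_control, cfg.n_control),
        ("depressed", truth_depressed, cfg.n_depressed),
    ):
        cov = pcor_to_covariance(net)
        thr = [thresholds_from_cumprobs(cfg.gses_cumprobs[name])] * len(GSES_ITEMS)
        thr += [thresholds_from_cumprobs(cfg.phq9_cumprobs[name])] * len(PHQ9_ITEMS)
        mins = [1] * len(GSES_ITEMS) + [0] * len(PHQ9_ITEMS)
        sample = sample_likert(
            cov, thr, n,
            seed=rng_for(cfg.seed, f"likert-{name}").integers(2**31),
            category_mins=mins, labels=STUDY_ITEMS,
        )
        frame = sample.frame
        if cfg.covariates:
            rng = rng_for(cfg.seed, f"covariates-{name}")
            mu, sd = AGE_PROFILE[name]
            frame["age"] = np.clip(np.round(rng.normal(mu, sd, n)), 12, 18).astype(int)
            frame["gender"] = (rng.random(n) < FEMALE_RATE[name]).astype(int)
            edu_p = np.asarray(EDUCATION_PROBS[name], dtype=float)
            frame["education"] = rng.choice([1, 2, 3], size=n, p=edu_p / edu_p.sum())
        frames[name] = frame

    return SimulatedStudy(cfg, truth_control, truth_depressed,
                          frames["control"], frames["depressed"])


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Write data CSV, ground-truth edge list and a JSON manifest."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data_path = out / "study_data.csv"
    combined = study.combined_frame()
    combined.columns = [c.lower() for c in combined.columns]
    combined.to_csv(data_path, index=False)

    rows = []
    for name, net in (("control", study.truth_control),
                      ("depressed", study.truth_depressed)):
        iu, ju = np.triu_indices(net.p, 1)
        for i, j in zip(iu, ju):
            w = net.pcor[i, j]
            if w != 0.0:
                rows.append({
                    "group": name,
                    "node_i": net.labels[i],
                    "node_j": net.labels[j],
                    "weight": w,
                    "community_i": net.communities[net.labels[i]],
                    "community_j": net.communities[net.labels[j]],
                })
    import pandas as pd

    truth_path = out / "true_edges.csv"
    pd.DataFrame(rows).to_csv(truth_path, index=False)
    manifest = {"config": study.config.to_dict(), "items": STUDY_ITEMS}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {"data": str(data_path), "truth": str(truth_path),
            "manifest": str(manifest_path)}
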
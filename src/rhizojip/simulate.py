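"""Seeded generators with known ground truth.

Three generators feed the downstream stages:

* OJIP transients — a phenomenological three-exponential rise (J, I, P
  phases) plus an optional fast K component (time constant ~0.3 ms) whose
  amplitude mimics donor-side (OEC) impairment under saline-alkaline stress.
  This is a curve model with controllable cardinal-point values, not a
  mechanistic PSII energy-flux model.
* Genus abundance tables — Dirichlet-multinomial counts around a lognormal
  rank-abundance profile, with group-specific planted markers on chosen taxa.
* Physiology tables — indicators linearly linked to log10 relative abundance
  of designated taxa with Gaussian noise.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import AbundanceTable, FluorescenceTransient, GROUPS, logger

#: default measurement grid: 120 log-spaced points over a 1-s saturating pulse
DEFAULT_GRID_US = np.geomspace(20.0, 1.0e6, 120)

_LN2 = np.log(2.0)


@dataclass
class TransientParams:
    """Parameters of one synthetic OJIP rise curve.

    Phase weights ``wJ, wI, wP`` (summing to 1) and time constants in ms
    (``tauJ < tauI < tauP``) shape the J, I and P rise phases; ``kappa``
    adds a K-band component at ``tauK`` (~0.3 ms). Defaults give a healthy
    leaf: Fv/Fm = 0.8, VJ ~ 0.54.
    """

    F0: float = 400.0
    Fm: float = 2000.0
    wJ: float = 0.50
    wI: float = 0.25
    wP: float = 0.25
    tauJ: float = 0.6
    tauI: float = 8.0
    tauP: float = 120.0
    kappa: float = 0.0
    tauK: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.F0 <= 0:
            raise ValueError("F0 must be positive")
        if self.Fm <= self.F0:
            raise ValueError("Fm must exceed F0")
        w = np.array([self.wJ, self.wI, self.wP])
        if (w < 0).any():
            raise ValueError("phase weights must be non-negative")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("phase weights must sum to 1")
        if not (0 < self.tauJ < self.tauI < self.tauP):
            raise ValueError("time constants must satisfy 0 < tauJ < tauI < tauP")
        if self.kappa < 0 or self.tauK <= 0:
            raise ValueError("kappa must be >= 0 and tauK > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def phase_mixture(t_ms: np.ndarray, params: TransientParams) -> np.ndarray:
    """Unnormalized relative variable fluorescence V(t).

    V(0) = 0 and V(inf) -> 1 + kappa; non-decreasing for non-negative weights.
    """
    t = np.asarray(t_ms, dtype=float)
    v = (
        params.wJ * -np.expm1(-t / params.tauJ)
        + params.wI * -np.expm1(-t / params.tauI)
        + params.wP * -np.expm1(-t / params.tauP)
        + params.kappa * -np.expm1(-t / params.tauK)
    )
    return v


def simulate_transient(
    params: TransientParams,
    grid_us: np.ndarray | None = None,
    sample_id: str = "sim",
) -> FluorescenceTransient:
    """Simulate one induction curve on a time grid (microseconds).

    F(t) = F0 + (Fm - F0) * V(t - t1)/V(t_max - t1) + N(0, noise_sd), where
    t1 is the first grid instant: the variable rise is referenced to the
    first sampling point, mirroring the instrument convention that the
    earliest recorded point (~20 us) defines F0. With noise_sd = 0 the curve
    is deterministic, F(t1) = F0 and max F = Fm exactly.
    """
    grid = DEFAULT_GRID_US if grid_us is None else np.asarray(grid_us, float)
    if grid.min() < 10.0 or grid.max() > 2.0e6:
        raise ValueError("time grid must lie within [10 us, 2 s]")
    v = phase_mixture((grid - grid[0]) / 1000.0, params)
    v_norm = v / v[-1]
    f = params.F0 + (params.Fm - params.F0) * v_norm
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        f = f + rng.normal(0.0, params.noise_sd, size=f.shape)
    return FluorescenceTransient(sample_id, grid, f)


@dataclass
class ExperimentTruth:
    group_params: dict[str, TransientParams]
    sample_params: dict[str, TransientParams]


def simulate_experiment(
    n_per_group: int,
    control: TransientParams | None = None,
    deltas: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    cv: float = 0.05,
    grid_us: np.ndarray | None = None,
) -> tuple[list[FluorescenceTransient], pd.DataFrame, ExperimentTruth]:
    """Simulate the four-group (TN, TA, SN, SA) fluorescence experiment.

    ``deltas`` maps group -> additive shifts on TransientParams fields
    (e.g. raise ``kappa`` and lower ``Fm`` for stressed groups). Per-sample
    parameters get multiplicative lognormal jitter (default cv = 5%) on F0,
    the variable fluorescence span Fm - F0, and kappa. Returns the
    transients, the design table, and the generating ground truth.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    control = control or TransientParams()
    deltas = deltas or {}
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))

    group_params: dict[str, TransientParams] = {}
    for g in GROUPS:
        shifts = deltas.get(g, {})
        unknown = set(shifts) - set(control.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown parameter fields in deltas[{g!r}]: {unknown}")
        kw = {k: getattr(control, k) + dv for k, dv in shifts.items()}
        group_params[g] = replace(control, **kw)

    transients: list[FluorescenceTransient] = []
    rows = []
    sample_params: dict[str, TransientParams] = {}
    for g in GROUPS:
        gp = group_params[g]
        for i in range(n_per_group):
            sid = f"{g}{i + 1:02d}"
            jf0, jfv, jk = np.exp(rng.normal(-sigma**2 / 2, sigma, size=3))
            sp = replace(
                gp,
                F0=gp.F0 * jf0,
                Fm=gp.F0 * jf0 + (gp.Fm - gp.F0) * jfv,
                kappa=gp.kappa * jk,
                noise_sd=gp.noise_sd,
                seed=int(rng.integers(2**31)),
            )
            sample_params[sid] = sp
            transients.append(simulate_transient(sp, grid_us, sample_id=sid))
            rows.append({"sample_id": sid, "variety": g[0], "soil": g[1], "group": g})
            logger.debug("simulated transient %s with seed %d", sid, sp.seed)
    design = pd.DataFrame(rows)
    return transients, design, ExperimentTruth(group_params, sample_params)


# ---------------------------------------------------------------------------
# community
# ---------------------------------------------------------------------------


@dataclass
class PlantedMarker:
    """A taxon enriched in one group by ``log2_effect`` doublings."""

    taxon: int
    group: str
    log2_effect: float


@dataclass
class CommunityParams:
    """Dirichlet-multinomial community generator settings.

    The default base profile is a deterministic lognormal rank-abundance
    curve (sigma = 1.5 natural-log units); ``theta`` is the overdispersion
    of the Dirichlet (concentrations = proportions / theta).
    """

    n_taxa: int = 150
    n_per_group: int = 6
    depth: int = 100_000
    base_log_abundance: np.ndarray | None = None
    markers: tuple[PlantedMarker, ...] = field(default_factory=tuple)
    theta: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if self.theta <= 0:
            raise ValueError("overdispersion theta must be positive")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")

    def base_profile(self) -> np.ndarray:
        if self.base_log_abundance is not None:
            base = np.asarray(self.base_log_abundance, float)
            if base.size != self.n_taxa:
                raise ValueError("base_log_abundance length must equal n_taxa")
            return base
        q = (np.arange(self.n_taxa) + 0.5) / self.n_taxa
        return norm.ppf(1.0 - q) * 1.5


def _default_lineage(i: int) -> str:
    return (
        f"k__Bacteria;p__Phylum{i % 12:02d};c__Class{i % 12:02d};"
        f"o__Order{i % 30:02d};f__Family{i % 60:02d};"
        f"g__Genus{i:03d};s__Species{i:03d}"
    )


def make_design(n_per_group: int, prefix: str = "") -> pd.DataFrame:
    rows = [
        {"sample_id": f"{prefix}{g}{i + 1:02d}", "variety": g[0], "soil": g[1], "group": g}
        for g in GROUPS
        for i in range(n_per_group)
    ]
    return pd.DataFrame(rows)


def simulate_abundance(
    params: CommunityParams, design: pd.DataFrame | None = None
) -> AbundanceTable:
    """Draw a samples x taxa count table with planted group effects.

    Per sample, relative abundances are Dirichlet with concentrations
    proportional to exp(base + group effects) / theta, and counts are a
    multinomial draw at the stated depth, so every row sums to the depth
    exactly.
    """
    if design is None:
        design = make_design(params.n_per_group)
    base = params.base_profile()
    for m in params.markers:
        if not 0 <= m.taxon < params.n_taxa:
            raise ValueError(f"marker taxon index {m.taxon} out of range")
        if m.group not in set(design["group"]):
            raise ValueError(f"marker group {m.group!r} absent from design")
    rng = np.random.default_rng(params.seed)
    taxa = [_default_lineage(i) for i in range(params.n_taxa)]
    rows = {}
    for _, rec in design.iterrows():
        eff = base.copy()
        for m in params.markers:
            if rec["group"] == m.group:
                eff[m.taxon] += m.log2_effect * _LN2
        w = np.exp(eff - eff.max())
        p = w / w.sum()
        prob = rng.dirichlet(p / params.theta)
        rows[rec["sample_id"]] = rng.multinomial(params.depth, prob)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    counts = counts.loc[list(design["sample_id"])]
    return AbundanceTable(counts)


# ---------------------------------------------------------------------------
# physiology linkage
# ---------------------------------------------------------------------------


@dataclass
class LinkageParams:
    """Linear link: indicator = alpha + beta*log10(rel. abundance + 1/depth) + noise."""

    indicator: str
    taxon: str
    beta: float
    alpha: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sd must be >= 0")


def simulate_physiology(
    design: pd.DataFrame,
    table: AbundanceTable,
    linkages: list[LinkageParams],
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a long physiology table linked to taxa in ``table``.

    The pseudocount is 1/depth (per-sample row sum), which avoids -inf
    while preserving rank order among nonzero counts.
    """
    rng = np.random.default_rng(seed)
    rel = table.values.div(table.row_sums(), axis=0)
    pseudo = 1.0 / table.row_sums()
    rows = []
    for link in linkages:
        if link.taxon not in table.values.columns:
            raise ValueError(f"linked taxon {link.taxon!r} not in abundance table")
        x = np.log10(rel[link.taxon] + pseudo)
        vals = link.alpha + link.beta * x
        if link.sigma > 0:
            vals = vals + rng.normal(0.0, link.sigma, size=len(vals))
        for sid, v in zip(rel.index, np.asarray(vals, float)):
            rows.append({"sample_id": sid, "indicator": link.indicator, "value": v})
    out = pd.DataFrame(rows)
    missing = set(out["sample_id"]) - set(design["sample_id"])
    if missing:
        raise ValueError(f"abundance samples not in design: {sorted(missing)}")
    return out
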
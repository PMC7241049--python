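"""Domain containers shared across the pipeline.

Concentrations are µM throughout; rates are nmol per m² sediment surface per
hour; volumes are mL; depths are cm; areas are m². A µM concentration times a
mL volume is an amount in nmol, which keeps the chamber mass balance free of
unit conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Site",
    "DepthProfile",
    "ChamberConfig",
    "SamplingEvent",
    "IncubationSeries",
    "RatePoint",
    "KineticFit",
    "OtuTable",
    "OrdinationResult",
    "LandscapeResult",
    "AssociationResult",
]


@dataclass
class Site:
    """One stream site: land cover, geochemistry and dissolved gases.

    ``ch4_stream``/``ch4_pore`` etc. are streamwater and porewater
    concentrations in µM.
    """

    site_id: str
    altitude: float
    temperature: float
    ph: float
    land_cover: dict[str, float]
    ion_conc: dict[str, float]
    doc: float
    ch4_stream: float
    ch4_pore: float
    co2_stream: float
    co2_pore: float
    do_stream: float
    do_pore: float

    def __post_init__(self) -> None:
        total = sum(self.land_cover.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"site {self.site_id}: land-cover fractions sum to {total}, not 1"
            )
        for name, frac in self.land_cover.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"site {self.site_id}: cover fraction {name}={frac}")
        for attr in ("ch4_stream", "ch4_pore", "co2_stream", "co2_pore",
                     "do_stream", "do_pore", "doc"):
            if getattr(self, attr) < 0:
                raise ValueError(f"site {self.site_id}: negative {attr}")


@dataclass
class DepthProfile:
    """Vertical porewater profile; depth 0 is the streamwater endpoint."""

    site_id: str
    depth: np.ndarray  # cm, strictly increasing, starts at 0
    ch4: np.ndarray
    co2: np.ndarray
    do: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.ch4 = np.asarray(self.ch4, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        self.do = np.asarray(self.do, dtype=float)
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depths must be strictly increasing")
        for name in ("ch4", "co2", "do"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"negative {name} concentration in profile")


@dataclass
class ChamberConfig:
    """Closed incubation chamber geometry and protocol.

    The default geometry is a 760 cm³ headspace-free Plexiglas cylinder
    (11 cm diameter × 8 cm) loaded with ~25 g wet sediment; 30 mL of water is
    withdrawn at each measurement and replaced with air-equilibrated
    streamwater. Sediment surface area is wet mass × specific surface area
    and is the normalisation basis for all rates.
    """

    volume_ml: float = 760.0
    sediment_mass_g: float = 25.0
    specific_area_m2_per_g: float = 1.0
    sediment_bulk_density_g_cm3: float = 1.6
    withdrawal_ml: float = 30.0
    temperature: float = 20.0
    ch4_amendment_atm: float = 0.01  # 1 % CH4 in the equilibration headspace
    # replacement water: air-equilibrated streamwater
    repl_ch4: float = 0.003
    repl_co2: float = 16.0
    repl_o2: float = 284.0
    init_co2: float = 16.0
    init_o2: float = 284.0
    cue: float = 0.5
    co2_per_ch4: float = 1.0
    o2_per_ch4: Optional[float] = None  # default 2(1-CUE)+CUE

    def __post_init__(self) -> None:
        if self.withdrawal_ml >= self.volume_ml:
            raise ValueError("withdrawal volume must be below chamber volume")
        if self.o2_per_ch4 is None:
            self.o2_per_ch4 = 2.0 * (1.0 - self.cue) + 1.0 * self.cue

    @property
    def sediment_area_m2(self) -> float:
        return self.sediment_mass_g * self.specific_area_m2_per_g

    @property
    def water_volume_ml(self) -> float:
        return self.volume_ml - self.sediment_mass_g / self.sediment_bulk_density_g_cm3


@dataclass
class SamplingEvent:
    """Withdrawal/replacement at a sampling time (all volumes mL, conc µM)."""

    time_h: float
    withdrawn_ml: float
    repl_conc: dict[str, float]  # analyte -> replacement concentration


@dataclass
class IncubationSeries:
    """Measured concentration time series for one chamber plus its event ledger."""

    chamber_id: str
    site_id: str
    replicate: int
    is_blank: bool
    sediment_area: float  # m²; 0 for blanks
    water_volume: float  # mL
    times: np.ndarray  # h
    conc: dict[str, np.ndarray]  # analyte -> µM at `times`
    events: list[SamplingEvent] = field(default_factory=list)
    # populated by the simulator only (ground truth; never used by fitters)
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"chamber {self.chamber_id}: times not strictly increasing")
        for analyte, series in self.conc.items():
            series = np.asarray(series, dtype=float)
            if series.shape != self.times.shape:
                raise ValueError(f"{analyte} series length mismatch")
            if np.any(series < 0):
                raise ValueError(f"negative {analyte} concentration")
            self.conc[analyte] = series
        lo, hi = self.times[0], self.times[-1]
        for ev in self.events:
            if not (lo - 1e-9 <= ev.time_h <= hi + 1e-9):
                raise ValueError(
                    f"event at t={ev.time_h} h outside series range [{lo}, {hi}]"
                )


@dataclass
class RatePoint:
    """An interval-representative (S, V) pair for pointwise kinetics."""

    S: float  # µM
    V: float  # nmol m⁻² h⁻¹ (or nmol chamber⁻¹ h⁻¹ before normalisation)

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError("substrate concentration must be >= 0")


@dataclass
class KineticFit:
    """Michaelis–Menten parameters for one site with fit diagnostics."""

    site_id: str
    v_max: float  # nmol m⁻² h⁻¹
    k_s: float  # µM
    rss: float
    se_vmax: float
    se_ks: float
    converged: bool
    mode: str  # "trajectory" | "pointwise"
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.v_max < 0 or self.k_s < 0:
            raise ValueError("V_max and K_S must be non-negative")
        if self.converged and not (np.isfinite(self.v_max) and np.isfinite(self.k_s)):
            raise ValueError("converged fit must have finite estimates")


@dataclass
class OtuTable:
    """Sites × OTUs count table with taxonomy and methanotroph flags."""

    counts: "pd.DataFrame"  # rows = sites, columns = OTU ids, integer counts
    taxonomy: "pd.Series"  # OTU id -> ranked lineage string
    is_mob: "pd.Series"  # OTU id -> bool

    def __post_init__(self) -> None:
        import pandas as pd  # local to keep module import light

        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if (self.counts.values < 0).any():
            raise ValueError("negative counts in OTU table")
        missing = set(self.counts.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"taxonomy missing for OTUs: {sorted(missing)[:5]} ...")
        self.is_mob = self.is_mob.reindex(self.counts.columns).fillna(False).astype(bool)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def site_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class OrdinationResult:
    """Scores from an ordination (nMDS or PCA)."""

    sample_scores: "pd.DataFrame"  # sites × k
    species_scores: Optional["pd.DataFrame"]  # OTUs × k (nMDS) or loadings (PCA)
    stress: float  # Kruskal stress-1 for nMDS; nan for PCA
    explained: Optional[np.ndarray]  # PCA variance fractions; None for nMDS
    method: str
    converged: bool = True
    stress_history: Optional[list[np.ndarray]] = None  # per-restart stress traces


@dataclass
class LandscapeResult:
    """Community landscape: density grid, peaks, MOB clusters, hulls."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray  # shape (len(grid_y), len(grid_x))
    peaks: list[dict]  # {"x", "y", "height"}
    mob_clusters: "pd.Series"  # MOB OTU id -> {1, 2, ..., 0 = unassigned}
    hull_members: dict[int, list[str]]  # cluster -> non-MOB OTU ids inside hull
    overrep: dict[int, "pd.DataFrame"]  # cluster -> taxon shares table
    excluded_sites: list[str] = field(default_factory=list)


@dataclass
class AssociationResult:
    """OLS association between two per-site quantities."""

    predictor: str
    response: str
    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    excluded_sites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 outside [0, 1]")
        if self.n < 3:
            raise ValueError("need at least 3 sites")
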
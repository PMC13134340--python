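"""Seeded simulator of the nationwide grid-sampling design.

The survey design being emulated: the study region is divided into a
lattice of rectangular grids (default 162 grids of 11.062 km × 13.902 km);
within each grid two sites are placed at least 10 km apart; at each site
one pooled soil sample is taken per host tree genus (Pinus and Quercus),
each pooled from nine subsamples (three trees × three directions).  The
default configuration therefore yields 162 × 2 × 2 = 648 samples.

Phylotypes are simulated with known ground truth: a geographic range
(a disc in the planar design space, or widespread), a per-sample detection
probability modulated by host bias and covariate effects through a
logistic link, and ASV-type counts drawn as 1 + Poisson(λ) for detected
samples.  Because the truth is known, every downstream stage (range
metrics, red-list categorization, preference statistics) can be tested by
parameter recovery without external data.

The planar design is mapped to synthetic latitude/longitude by inverse
equal-area projection around a configurable centre (default 36°N, 128°E),
so the full geographic pipeline — projection included — is exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import Host, IncidenceTable, SampleRecord, SampleTable
from .range_metrics import OccurrenceSet, inverse_project, project_points, range_metrics_for
from .redlist import (Category, PopulationEstimate, ThresholdTable,
                      assess_phylotype, MATURE_INDIVIDUAL_MULTIPLIER, POOLING_FACTOR)

__all__ = [
    "DesignConfig",
    "TruthRecord",
    "generate_design",
    "design_planar",
    "generate_phylotypes",
    "expected_category",
    "grid_standardization_factor",
    "make_truth_suite",
    "write_truth",
]


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the grid sampling design (defaults match the survey)."""

    n_grids: int = 162
    grid_width_km: float = 11.062
    grid_height_km: float = 13.902
    sites_per_grid: int = 2
    min_site_separation_km: float = 10.0
    hosts: tuple[Host, ...] = (Host.PINUS, Host.QUERCUS)
    samples_per_host: int = 1
    subsamples_per_pool: int = 9  # 3 trees × 3 directions, pooled
    center: tuple[float, float] = (36.0, 128.0)  # lat, lon of design centre
    seed: int = 0

    def __post_init__(self) -> None:
        diag = math.hypot(self.grid_width_km, self.grid_height_km)
        if self.sites_per_grid > 1 and self.min_site_separation_km >= diag:
            raise ValueError(
                f"min_site_separation_km={self.min_site_separation_km} cannot fit "
                f"inside a grid of diagonal {diag:.3f} km"
            )
        if min(self.n_grids, self.sites_per_grid, self.samples_per_host) < 1:
            raise ValueError("all design counts must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_grids * self.sites_per_grid * len(self.hosts) * self.samples_per_host

    def lattice_shape(self) -> tuple[int, int]:
        """(n_cols, n_rows) of the grid lattice, chosen to keep the overall
        study region roughly square."""
        ncols = max(1, round(math.sqrt(self.n_grids * self.grid_height_km / self.grid_width_km)))
        nrows = math.ceil(self.n_grids / ncols)
        return ncols, nrows

    def extent_km(self) -> tuple[float, float]:
        ncols, nrows = self.lattice_shape()
        return ncols * self.grid_width_km, nrows * self.grid_height_km


@dataclass
class TruthRecord:
    """Ground truth for one simulated phylotype.

    ``range_center``/``range_radius_km`` define a disc in the planar design
    space; ``widespread`` overrides them to cover the whole region.
    ``detection_prob`` is the baseline per-sample detection probability
    inside the range; ``host_bias`` shifts the detection logit by +bias for
    Pinus and −bias for Quercus samples; ``covariate_effects`` shift it by
    effect × standardized covariate.  Detected samples draw ASV-type
    counts as 1 + Poisson(asv_lambda · exp(Σ abundance_effects · z)):
    ``abundance_effects`` modulate the count intensity through a log link.
    A covariate effect confined to detection is invisible to rclr-based
    correlation (zeros stay missing there), so an effect the preference
    stage is meant to recover must act on abundance.
    """

    phylotype_id: str
    genus: str = ""
    widespread: bool = False
    range_center: tuple[float, float] | None = None  # planar km
    range_radius_km: float = 0.0
    detection_prob: float = 0.9
    host_bias: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    abundance_effects: dict[str, float] = field(default_factory=dict)
    asv_lambda: float = 1.0
    expected: Category | None = None


def generate_design(config: DesignConfig) -> SampleTable:
    """Generate the sample table of one simulated survey.

    Grid origins lie on a rectangular lattice; sites are placed uniformly
    within their grid by rejection sampling until the pairwise separation
    constraint holds.  Covariates are drawn from simple climate/soil
    models: MAT declines with latitude and altitude, MAP and the soil
    chemistry variables are log-normal, pH is normal.  Deterministic for a
    given config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    ncols, _ = config.lattice_shape()
    ext_x, ext_y = config.extent_km()
    records: list[SampleRecord] = []
    for g in range(config.n_grids):
        col, row = g % ncols, g // ncols
        x0 = col * config.grid_width_km - ext_x / 2.0
        y0 = row * config.grid_height_km - ext_y / 2.0
        sites = _place_sites(rng, config, x0, y0)
        for s, (sx, sy) in enumerate(sites):
            (lat, lon), = inverse_project([[sx, sy]], config.center)
            covars = _draw_covariates(rng, lat)
            for host in config.hosts:
                for k in range(config.samples_per_host):
                    suffix = f"-{k + 1}" if config.samples_per_host > 1 else ""
                    records.append(SampleRecord(
                        sample_id=f"G{g + 1:03d}-S{s + 1}-{host.value[0]}{suffix}",
                        site_id=f"G{g + 1:03d}-S{s + 1}",
                        grid_id=f"G{g + 1:03d}",
                        host=host,
                        latitude=float(lat),
                        longitude=float(lon),
                        covariates=dict(covars),
                    ))
    return SampleTable(records)


def _place_sites(rng, config: DesignConfig, x0: float, y0: float,
                 max_tries: int = 1000) -> list[tuple[float, float]]:
    for _ in range(max_tries):
        xs = x0 + rng.uniform(0, config.grid_width_km, config.sites_per_grid)
        ys = y0 + rng.uniform(0, config.grid_height_km, config.sites_per_grid)
        pts = list(zip(xs, ys))
        if config.sites_per_grid == 1:
            return pts
        ok = all(math.dist(pts[i], pts[j]) >= config.min_site_separation_km
                 for i in range(len(pts)) for j in range(i + 1, len(pts)))
        if ok:
            return pts
    raise RuntimeError(
        f"could not place {config.sites_per_grid} sites >= "
        f"{config.min_site_separation_km} km apart in {max_tries} tries"
    )


def _draw_covariates(rng, lat: float) -> dict[str, float]:
    altitude = float(np.exp(rng.normal(5.3, 0.6)))  # median ~200 m
    mat = 16.5 - 0.75 * (lat - 33.0) - 6.5 * altitude / 1000.0 + rng.normal(0.0, 0.4)
    return {
        "MAT": round(mat, 2),
        "MAP": round(float(np.exp(rng.normal(np.log(1300.0), 0.15))), 1),
        "altitude": round(altitude, 1),
        "pH": round(float(np.clip(rng.normal(5.5, 0.5), 3.5, 8.5)), 2),
        "TOC": round(float(np.exp(rng.normal(np.log(30.0), 0.5))), 2),
        "TN": round(float(np.exp(rng.normal(np.log(2.5), 0.5))), 3),
        "NH4+": round(float(np.exp(rng.normal(np.log(10.0), 0.6))), 2),
        "NO3-": round(float(np.exp(rng.normal(np.log(8.0), 0.7))), 2),
        "TP": round(float(np.exp(rng.normal(np.log(500.0), 0.4))), 1),
    }


def design_planar(samples: SampleTable, center: tuple[float, float] = (36.0, 128.0)) -> np.ndarray:
    """Planar km coordinates of each sample around the design centre."""
    return project_points([(r.latitude, r.longitude) for r in samples], center=center)


def _in_range(truth: TruthRecord, planar: np.ndarray) -> np.ndarray:
    if truth.widespread:
        return np.ones(len(planar), dtype=bool)
    if truth.range_center is None:
        raise ValueError(f"{truth.phylotype_id}: range_center required unless widespread")
    d = np.hypot(planar[:, 0] - truth.range_center[0], planar[:, 1] - truth.range_center[1])
    return d <= truth.range_radius_km


def generate_phylotypes(
    samples: SampleTable,
    truths: list[TruthRecord],
    seed: int,
    center: tuple[float, float] = (36.0, 128.0),
) -> IncidenceTable:
    """Simulate the phylotype × sample ASV-type incidence matrix.

    Detection for sample i inside the range follows
    ``logit p_i = logit(detection_prob) + host_bias·h_i + Σ_v effect_v·z_vi``
    with h = +1 (Pinus) / −1 (Quercus) / 0 and z the standardized
    covariate.  Samples outside the range are always 0.
    """
    rng = np.random.default_rng(seed)
    planar = design_planar(samples, center)
    hosts = np.array([{"PINUS": 1.0, "QUERCUS": -1.0}.get(r.host.value, 0.0)
                      for r in samples])
    zcov: dict[str, np.ndarray] = {}
    matrix = np.zeros((len(truths), len(samples)), dtype=np.int64)
    for ti, truth in enumerate(truths):
        mask = _in_range(truth, planar)
        p0 = np.clip(truth.detection_prob, 1e-9, 1 - 1e-9)
        logit = np.full(len(samples), math.log(p0 / (1 - p0)))
        if truth.host_bias:
            logit += truth.host_bias * hosts
        for var, eff in truth.covariate_effects.items():
            if var not in zcov:
                zcov[var] = _standardized_covariate(samples, var)
            logit += eff * zcov[var]
        p = 1.0 / (1.0 + np.exp(-logit))
        detected = mask & (rng.random(len(samples)) < p)
        n_det = int(detected.sum())
        if n_det:
            log_lam = np.full(len(samples), math.log(max(truth.asv_lambda, 1e-12)))
            for var, eff in truth.abundance_effects.items():
                if var not in zcov:
                    zcov[var] = _standardized_covariate(samples, var)
                log_lam += eff * zcov[var]
            matrix[ti, detected] = 1 + rng.poisson(np.exp(log_lam[detected]))
    return IncidenceTable(
        [t.phylotype_id for t in truths],
        [t.genus for t in truths],
        samples.sample_ids,
        matrix,
    )


def _standardized_covariate(samples: SampleTable, var: str) -> np.ndarray:
    if var == "latitude":
        vals = np.array([r.latitude for r in samples])
    elif var == "longitude":
        vals = np.array([r.longitude for r in samples])
    else:
        vals = np.array([r.covariates.get(var, np.nan) for r in samples], dtype=float)
    mu, sd = np.nanmean(vals), np.nanstd(vals)
    z = (vals - mu) / (sd if sd > 0 else 1.0)
    return np.where(np.isnan(z), 0.0, z)


def grid_standardization_factor(config: DesignConfig, cell_km: float = 2.0) -> float:
    """AOO correction factor standardizing site-level cell occupancy to the
    sampling-grid grain: grid area / (sites per grid × cell area).

    With two point sites per ~154 km² grid, raw 2-km cell occupancy
    understates the area a detection represents by roughly this factor.
    """
    return (config.grid_width_km * config.grid_height_km
            / (config.sites_per_grid * cell_km * cell_km))


def expected_category(
    truth: TruthRecord,
    samples: SampleTable,
    thresholds: ThresholdTable | None = None,
    cell_km: float = 2.0,
    correction_factor: float = 1.0,
    center: tuple[float, float] = (36.0, 128.0),
) -> Category:
    """Analytic recovery target: the category implied by the generating
    range under complete detection.

    Takes the hull/cell geometry of every sample reachable by the range
    and the expected population size n_reachable × (1 + λ) × 10 × 12/7,
    then runs the same decision table used on realized data.
    """
    t = thresholds or ThresholdTable()
    planar = design_planar(samples, center)
    mask = _in_range(truth, planar)
    n_reach = int(mask.sum())
    expected_n = n_reach * (1.0 + truth.asv_lambda) * float(
        MATURE_INDIVIDUAL_MULTIPLIER * POOLING_FACTOR)
    if n_reach == 0:
        return Category.DD
    recs = [r for r, m in zip(samples, mask) if m]
    occ = OccurrenceSet(truth.phylotype_id, [(r.latitude, r.longitude) for r in recs])
    metrics = range_metrics_for(occ, cell_km, correction_factor)
    pop = PopulationEstimate(truth.phylotype_id, expected_n)
    return assess_phylotype(metrics, pop, t).category_final


def make_truth_suite(
    samples: SampleTable,
    n_per_category: dict[Category, int],
    rng: np.random.Generator,
    detection_prob: float = 0.98,
    center: tuple[float, float] = (36.0, 128.0),
) -> list[TruthRecord]:
    """Construct truth records targeting given red-list categories.

    Ranges are placed so the implied geometry falls well inside the target
    category's area band and the expected population size is far from the
    500-individual eligibility boundary:

    * DD — a single site, low λ (expected N ≈ 50);
    * CR — a single site, high λ (eligible; 1 occupied cell → AOO 4 km²);
    * EN — disc of radius ~18 km (EOO a few hundred to a few thousand km²);
    * VU — disc of radius ~60 km centred in the design interior;
    * LC — widespread (to be assessed with the grid-standardized
      correction factor, under which full occupancy clears the VU bounds).

    EN and VU discs are centred only on sites whose neighbourhood holds
    enough other sites (≥12 within 18 km, ≥100 within 60 km) so the
    expected population size sits far above the 500-individual gate —
    eligibility is part of the category the record encodes, not left to
    Poisson luck at the boundary.  The realized category of each record is
    whatever :func:`expected_category` computes for it; the targets steer
    coverage, they are not asserted here.
    """
    planar = design_planar(samples, center)
    site_xy: dict[str, np.ndarray] = {}
    for rec, xy in zip(samples, planar):
        site_xy.setdefault(rec.site_id, xy)
    sites = np.array(list(site_xy.values()))
    dists = np.hypot(sites[:, 0, None] - sites[None, :, 0],
                     sites[:, 1, None] - sites[None, :, 1])

    def dense_pool(radius: float, min_neighbors: int) -> np.ndarray:
        counts = (dists <= radius).sum(axis=1)
        pool = sites[counts >= min_neighbors]
        return pool if len(pool) else sites

    pools = {Category.EN: dense_pool(18.0, 12), Category.VU: dense_pool(60.0, 100)}
    truths: list[TruthRecord] = []
    idx = 0
    for cat, n in n_per_category.items():
        for _ in range(n):
            idx += 1
            pid = f"sim-{cat.value}-{idx:04d}"
            if cat is Category.LC:
                truths.append(TruthRecord(pid, widespread=True, asv_lambda=1.0,
                                          detection_prob=detection_prob))
                continue
            if cat in (Category.DD, Category.CR):
                c = sites[rng.integers(len(sites))]
                lam = 0.5 if cat is Category.DD else 30.0
                truths.append(TruthRecord(pid, range_center=(float(c[0]), float(c[1])),
                                          range_radius_km=0.5, asv_lambda=lam,
                                          detection_prob=detection_prob))
                continue
            pool = pools[cat]
            c = pool[rng.integers(len(pool))]
            radius = 18.0 if cat is Category.EN else 60.0
            truths.append(TruthRecord(pid, range_center=(float(c[0]), float(c[1])),
                                      range_radius_km=radius, asv_lambda=2.0,
                                      detection_prob=detection_prob))
    return truths


def realized_category(
    incidence: IncidenceTable,
    index: int,
    samples: SampleTable,
    thresholds: ThresholdTable | None = None,
    cell_km: float = 2.0,
    correction_factor: float = 1.0,
) -> Category:
    """Category assigned to one simulated phylotype from its realized data.

    A phylotype never detected has population size 0 and is Data Deficient.
    """
    counts = incidence.asv_types[index]
    pid = incidence.phylotype_ids[index]
    pop = _estimate(counts, incidence.sample_ids, pid)
    present = counts > 0
    if not present.any():
        return Category.DD
    recs = [samples[sid] for sid, p in zip(incidence.sample_ids, present) if p]
    occ = OccurrenceSet(pid, [(r.latitude, r.longitude) for r in recs])
    metrics = range_metrics_for(occ, cell_km, correction_factor)
    return assess_phylotype(metrics, pop, thresholds).category_final


def _estimate(counts, sample_ids, pid):
    from .redlist import estimate_population

    return estimate_population(counts, sample_ids, pid)


def write_truth(truths: list[TruthRecord], path, header_comments=()) -> None:
    """Write the ground-truth table as TSV for test harnesses."""
    import pandas as pd

    rows = []
    for t in truths:
        rows.append({
            "phylotype": t.phylotype_id, "genus": t.genus,
            "widespread": t.widespread,
            "center_x_km": t.range_center[0] if t.range_center else "",
            "center_y_km": t.range_center[1] if t.range_center else "",
            "radius_km": t.range_radius_km,
            "detection_prob": t.detection_prob,
            "host_bias": t.host_bias,
            "asv_lambda": t.asv_lambda,
            "covariate_effects": ";".join(f"{k}={v}" for k, v in t.covariate_effects.items()),
            "expected_category": t.expected.value if t.expected else "",
        })
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
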
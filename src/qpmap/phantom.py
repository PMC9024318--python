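"""Digital phantoms and synthetic cohorts.

The imaging phantom is a brain-like concentric-shell geometry on a small 3-D
grid: an ellipsoidal "brain" whose outer rim is cortex and whose core is
white matter, with an embedded ellipsoidal hippocampus and a white-matter
lesion ("WMH") blob. Every region carries ground-truth k_W, CBF, ATT and R1b
means with optional within-region spread (truncated-normal per voxel), so the
whole estimation pipeline can be exercised and scored against known truth
without scanner data. Default regional means are the cohort values reported
for this technique (cortex k_W 81.51 / white matter 75.19 1/min; cortex CBF
39.60 / white matter 32.47 mL/100 g/min).

Acquisition simulation evaluates the forward model encode by encode and adds
Gaussian noise on the difference signal with SD ``noise_sd / sqrt(NEX_i)``
(the difference of two high-SNR magnitude images is approximately Gaussian).
"Difference-image SNR" is defined as the mean cortical signal of the crushed
b = 20, PLD = 1.5 s encode divided by ``noise_sd`` at NEX = 1.

The cohort generator draws per-subject covariates (age, sex, vascular-risk
count) and regional outcome means from a linear model, mirroring the
regression structure used in the downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import AcquisitionSpec, forward_series_batch

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "make_phantom",
    "simulate_acquisition",
    "noise_sd_for_snr",
    "make_cohort",
    "DEFAULT_REGIONS",
]

# sampling bounds for per-voxel truths (match the fitter's box constraints)
_TRUTH_BOUNDS = {"kw": (0.0, 500.0), "cbf": (0.0, 200.0), "att": (0.3, 3.0), "r1b": (0.1, 3.0)}


@dataclass(frozen=True)
class RegionSpec:
    """Ground-truth parameter distribution of one labeled region."""

    label: int
    name: str
    kw: float
    cbf: float
    att: float
    r1b: float
    kw_sd: float = 0.0
    cbf_sd: float = 0.0
    att_sd: float = 0.0
    r1b_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError("region labels must be positive integers")
        for key in ("kw", "cbf", "att", "r1b"):
            lo, hi = _TRUTH_BOUNDS[key]
            v = getattr(self, key)
            if not lo <= v <= hi:
                raise ValueError(f"{self.name}.{key}={v} outside sampling bounds [{lo}, {hi}]")
        if min(self.kw_sd, self.cbf_sd, self.att_sd, self.r1b_sd) < 0:
            raise ValueError("within-region SDs must be nonnegative")


# cortex/white-matter k_W and CBF means follow the reported cohort values;
# R1b defaults are typical 3 T tissue rates; ATT and the hippocampus/WMH
# regions use representative physiologic values.
DEFAULT_REGIONS: tuple[RegionSpec, ...] = (
    RegionSpec(1, "cortex", kw=81.51, cbf=39.60, att=1.2, r1b=0.77,
               kw_sd=4.0, cbf_sd=2.0, att_sd=0.05, r1b_sd=0.02),
    RegionSpec(2, "white_matter", kw=75.19, cbf=32.47, att=1.4, r1b=1.15,
               kw_sd=4.0, cbf_sd=2.0, att_sd=0.05, r1b_sd=0.02),
    RegionSpec(3, "hippocampus", kw=80.0, cbf=38.0, att=1.3, r1b=0.77,
               kw_sd=4.0, cbf_sd=2.0, att_sd=0.05, r1b_sd=0.02),
    RegionSpec(4, "wmh", kw=60.0, cbf=25.0, att=1.6, r1b=1.0,
               kw_sd=4.0, cbf_sd=2.0, att_sd=0.05, r1b_sd=0.02),
)


@dataclass(frozen=True)
class PhantomSpec:
    dims: tuple[int, int, int] = (20, 20, 10)
    voxel_size: tuple[float, float, float] = (1.9, 1.9, 4.0)
    regions: tuple[RegionSpec, ...] = DEFAULT_REGIONS
    noise_sd: float = 0.0
    m0_value: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if any(d < 4 for d in self.dims):
            raise ValueError("phantom grid must be at least 4 voxels per axis")


@dataclass
class PhantomTruth:
    """Label volume plus co-registered ground-truth parameter maps."""

    labels: np.ndarray
    kw: np.ndarray
    cbf: np.ndarray
    att: np.ndarray
    r1b: np.ndarray
    m0: np.ndarray
    voxel_size: tuple[float, float, float]
    names: dict[int, str]

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


# normalized-coordinate geometry: brain ellipsoid with a cortical rim and
# embedded blobs (centre, radii in [-1, 1] coordinates)
_BRAIN_RHO = 0.95
_CORE_RHO = 0.70
_BLOBS = {
    "hippocampus": ((0.25, 0.25, 0.0), (0.22, 0.22, 0.30)),
    "wmh": ((-0.30, -0.20, 0.0), (0.20, 0.20, 0.28)),
}


def make_phantom(spec: PhantomSpec | None = None) -> PhantomTruth:
    """Build the concentric-shell phantom with seeded per-voxel truths.

    Identical seed gives identical volumes; zero within-region SDs give
    piecewise-constant maps at the region means.
    """
    spec = spec or PhantomSpec()
    nx, ny, nz = spec.dims
    u = [np.linspace(-1, 1, n) for n in (nx, ny, nz)]
    ux, uy, uz = np.meshgrid(*u, indexing="ij")
    rho = np.sqrt(ux**2 + uy**2 + uz**2)

    by_name = {r.name: r for r in spec.regions}
    labels = np.zeros(spec.dims, dtype=np.int16)
    if "cortex" in by_name:
        labels[(rho <= _BRAIN_RHO) & (rho > _CORE_RHO)] = by_name["cortex"].label
    if "white_matter" in by_name:
        labels[rho <= _CORE_RHO] = by_name["white_matter"].label
    for name, (centre, radii) in _BLOBS.items():
        if name not in by_name:
            continue
        for c, r in zip(centre, radii):
            if abs(c) + r > 1.0:
                raise ValueError(f"region '{name}' exceeds the phantom grid")
        d = ((ux - centre[0]) / radii[0]) ** 2 + ((uy - centre[1]) / radii[1]) ** 2 \
            + ((uz - centre[2]) / radii[2]) ** 2
        labels[d <= 1.0] = by_name[name].label

    rng = np.random.default_rng(spec.seed)
    kw = np.zeros(spec.dims)
    cbf = np.zeros(spec.dims)
    att = np.full(spec.dims, _TRUTH_BOUNDS["att"][0])
    r1b = np.ones(spec.dims)
    maps = {"kw": kw, "cbf": cbf, "att": att, "r1b": r1b}
    for region in sorted(spec.regions, key=lambda r: r.label):
        sel = labels == region.label
        n = int(sel.sum())
        if n == 0:
            continue
        for key, vol in maps.items():
            mean = getattr(region, key)
            sd = getattr(region, f"{key}_sd")
            if sd == 0:
                vol[sel] = mean
            else:
                lo, hi = _TRUTH_BOUNDS[key]
                a, b = (lo - mean) / sd, (hi - mean) / sd
                vol[sel] = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                                               random_state=rng)
    m0 = np.where(labels > 0, spec.m0_value, 0.0)
    return PhantomTruth(labels=labels, kw=kw, cbf=cbf, att=att, r1b=r1b, m0=m0,
                        voxel_size=spec.voxel_size,
                        names={r.label: r.name for r in spec.regions})


def simulate_acquisition(truth: PhantomTruth, acq: AcquisitionSpec,
                         noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Noisy 4-D difference-signal series for ``truth`` under ``acq``.

    Encode i gets Gaussian noise with SD ``noise_sd / sqrt(NEX_i)``;
    ``noise_sd=0`` reproduces the noiseless forward series bit-exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    shape = truth.labels.shape
    clean = forward_series_batch(
        truth.kw.ravel(), truth.cbf.ravel(), truth.att.ravel(),
        truth.r1b.ravel(), truth.m0.ravel(), acq,
    ).reshape(shape + (len(acq),))
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    sd = noise_sd / np.sqrt(acq.nex)
    return clean + rng.standard_normal(clean.shape) * sd


def noise_sd_for_snr(truth: PhantomTruth, acq: AcquisitionSpec, snr: float,
                     region_label: int = 1) -> float:
    """Noise SD (at NEX = 1) giving the requested difference-image SNR.

    SNR is referenced to the mean signal of ``region_label`` (cortex by
    default) in the crushed encode nearest PLD = 1.5 s.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    plds = acq.plds
    crushed = acq.crushed
    candidates = np.flatnonzero(crushed)
    if candidates.size == 0:
        candidates = np.arange(len(acq))
    j = candidates[np.argmin(np.abs(plds[candidates] - 1.5))]
    sel = truth.labels == region_label
    if not sel.any():
        raise ValueError(f"label {region_label} absent from phantom")
    sig = forward_series_batch(
        truth.kw[sel], truth.cbf[sel], truth.att[sel],
        truth.r1b[sel], truth.m0[sel], acq,
    )[:, j].mean()
    return float(sig / snr)


@dataclass(frozen=True)
class CohortSpec:
    """Generating model of a synthetic subject cohort.

    Regional outcome means follow
    ``intercept + age_slope * (age / 10) + sex_effect * sex
    + risk_effect * risk_count + N(0, resid_sd)``
    with sex coded female = 1. Defaults mirror the reported cohort: 30
    subjects, 37% female, vascular-risk counts distributed (0,1,2,3) =
    (17,5,5,3)/30, cortical k_W intercept 95 with slope -4.43 per decade and
    residual SD 8.
    """

    n_subjects: int = 30
    age_range: tuple[float, float] = (25.0, 85.0)
    female_prop: float = 0.37
    risk_probs: tuple[float, ...] = (17 / 30, 5 / 30, 5 / 30, 3 / 30, 0.0)
    outcome: str = "kw_cortex"
    intercept: float = 95.0
    age_slope: float = -4.43
    sex_effect: float = 0.0
    risk_effect: float = -3.0
    resid_sd: float = 8.0
    wmh: bool = False
    wmh_logvol_mean: float = 6.0
    wmh_logvol_sd: float = 1.0
    wmh_kw_intercept: float = 110.0
    wmh_kw_slope: float = -8.0
    wmh_kw_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if self.resid_sd < 0:
            raise ValueError("residual SD must be nonnegative")
        if not np.isclose(sum(self.risk_probs), 1.0):
            raise ValueError("risk_probs must sum to 1")
        if len(self.risk_probs) > 5:
            raise ValueError("risk counts are limited to 0..4")


def make_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Seeded synthetic cohort table.

    Columns: subject_id, age (years), sex (female = 1), risk_count (0-4) and
    the regional outcome named by ``spec.outcome``; with ``spec.wmh`` also a
    lognormal WMH volume (mm^3) and a WMH k_W that declines with log volume.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    age = rng.uniform(*spec.age_range, size=n)
    sex = (rng.uniform(size=n) < spec.female_prop).astype(int)
    risk = rng.choice(len(spec.risk_probs), size=n, p=np.asarray(spec.risk_probs))
    outcome = (spec.intercept + spec.age_slope * (age / 10.0)
               + spec.sex_effect * sex + spec.risk_effect * risk
               + rng.normal(0.0, spec.resid_sd, size=n))
    df = pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "risk_count": risk,
        spec.outcome: outcome,
    })
    if spec.wmh:
        logvol = rng.normal(spec.wmh_logvol_mean, spec.wmh_logvol_sd, size=n)
        df["wmh_volume_mm3"] = np.exp(logvol)
        df["kw_wmh"] = (spec.wmh_kw_intercept + spec.wmh_kw_slope * logvol
                        + rng.normal(0.0, spec.wmh_kw_sd, size=n))
    return df
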
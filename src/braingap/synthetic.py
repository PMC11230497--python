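"""Synthetic cohorts: parcellated time series plus metadata and exposome tables.

Generative model for a subject's signal
---------------------------------------
Regions are partitioned into ``n_blocks`` contiguous blocks (stand-ins for
frontoposterior hubs vs. other systems).  Region r in block b at time t is

    x_r(t) = lam * f_b(t) + gam * g(t) + noise_sd * eps_r(t)

where f_b is a block-shared latent factor, g a global factor carrying the
long-range (cross-block) coupling and eps_r white noise.  Both loadings
decay linearly with the subject's *effective age*

    effective_age = age + group_age_offset[diagnosis] + lac_extra_offset * 1[region == LAC]
    lam(effective_age) = max(lam0 - coupling_slope * (effective_age - age_min), lam_floor)

so dependence (and hence within-block O-information) weakens monotonically
with effective age; diagnosis and LAC membership shift a brain "older" than
its chronological age.  A per-scanner multiplicative scale is applied last.
Shared factors induce redundancy (Omega > 0) within blocks; an optional
synergy triplet replaces one region by a scaled sum of two others.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hoi import RegionTimeSeries

__all__ = [
    "CohortConfig",
    "CohortRecord",
    "generate_cohort_table",
    "simulate_subject_timeseries",
    "generate_exposome_table",
    "simulate_bag_outcomes",
    "write_fixture_set",
]

GROUPS = ("HC", "MCI", "AD", "bvFTD")
REGIONS = ("LAC", "nonLAC")

_LAC_COUNTRIES = ("Argentina", "Chile", "Colombia", "Mexico", "Peru", "Brazil", "Cuba")
_NONLAC_COUNTRIES = ("USA", "China", "Japan", "Italy", "Turkey", "Greece", "UK", "Ireland")


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    n_subjects: int = 100
    n_regions: int = 82
    n_samples: int = 300
    sampling_rate_or_tr: float = 2.0
    modality: str = "fMRI"
    age_range: tuple[float, float] = (20.0, 90.0)
    group_mix: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.7, "MCI": 0.1, "AD": 0.1, "bvFTD": 0.1}
    )
    group_age_offset: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "MCI": 4.0, "AD": 8.0, "bvFTD": 7.0}
    )
    region_mix: dict[str, float] = field(
        default_factory=lambda: {"LAC": 0.5, "nonLAC": 0.5}
    )
    lac_extra_offset: float = 3.0
    n_blocks: int = 4
    lam0: float = 1.0
    lam_floor: float = 0.05
    coupling_slope: float = 0.008
    cross_coupling0: float = 0.45
    noise_sd: float = 1.0
    n_scanners: int = 3
    scanner_scale: float = 1.15
    plant_synergy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix in (("group_mix", self.group_mix), ("region_mix", self.region_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-8:
                raise ConfigurationError(f"{name} proportions must sum to 1")
            if any(p < 0 for p in mix.values()):
                raise ConfigurationError(f"{name} proportions must be non-negative")
        if set(self.group_mix) - set(GROUPS):
            raise ConfigurationError(f"unknown groups in group_mix: {self.group_mix}")
        if set(self.region_mix) - set(REGIONS):
            raise ConfigurationError(f"unknown regions in region_mix: {self.region_mix}")
        if self.n_regions < 4:
            raise ConfigurationError("n_regions must be >= 4")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigurationError("age_range must satisfy min < max")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        if self.n_samples < 10 * self.n_regions:
            warnings.warn(
                f"n_samples={self.n_samples} < 10 x n_regions={self.n_regions}; "
                "covariance estimates may be noisy",
                stacklevel=2,
            )

    def region_labels(self) -> list[str]:
        return [f"R{i:03d}" for i in range(self.n_regions)]


@dataclass
class CohortRecord:
    subject_id: str
    age: float
    sex: str
    diagnosis: str
    region: str
    country: str
    scanner: str
    eyes: str
    education: float
    modality: str = "fMRI"

    def effective_age(self, config: CohortConfig) -> float:
        off = config.group_age_offset.get(self.diagnosis, 0.0)
        lac = config.lac_extra_offset if self.region == "LAC" else 0.0
        return self.age + off + lac


def _largest_remainder(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Integer allocation of n items to categories by largest remainder."""
    keys = list(proportions)
    exact = np.array([proportions[k] * n for k in keys])
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    return dict(zip(keys, counts.tolist()))


def generate_cohort_table(config: CohortConfig) -> list[CohortRecord]:
    """Deterministic cohort metadata with largest-remainder group allocation."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    group_counts = _largest_remainder(config.group_mix, n)
    region_counts = _largest_remainder(config.region_mix, n)

    diagnoses = [g for g in GROUPS for _ in range(group_counts.get(g, 0))]
    regions = [r for r in REGIONS for _ in range(region_counts.get(r, 0))]
    rng.shuffle(diagnoses)
    rng.shuffle(regions)

    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n)
    sexes = rng.choice(["F", "M"], size=n)
    eyes = rng.choice(["open", "closed"], size=n)
    education = np.clip(rng.normal(12.0, 4.0, size=n), 0.0, 25.0)
    scanners = [f"scanner{rng.integers(config.n_scanners)}" for _ in range(n)]

    records = []
    for k in range(n):
        pool = _LAC_COUNTRIES if regions[k] == "LAC" else _NONLAC_COUNTRIES
        records.append(
            CohortRecord(
                subject_id=f"sub-{k:04d}",
                age=float(ages[k]),
                sex=str(sexes[k]),
                diagnosis=diagnoses[k],
                region=regions[k],
                country=str(pool[rng.integers(len(pool))]),
                scanner=scanners[k],
                eyes=str(eyes[k]),
                education=float(education[k]),
                modality=config.modality,
            )
        )
    return records


def _block_assignment(n_regions: int, n_blocks: int) -> np.ndarray:
    """Contiguous block index for each region."""
    return np.repeat(np.arange(n_blocks), -(-n_regions // n_blocks))[:n_regions]


def simulate_subject_timeseries(
    record: CohortRecord, config: CohortConfig, seed: int
) -> RegionTimeSeries:
    """One subject's regions x samples matrix under the latent-factor model."""
    rng = np.random.default_rng(seed)
    n_reg, n_t = config.n_regions, config.n_samples
    eff = record.effective_age(config)
    age_min = config.age_range[0]

    lam = max(config.lam0 - config.coupling_slope * (eff - age_min), config.lam_floor)
    gam = max(
        config.cross_coupling0 - 0.5 * config.coupling_slope * (eff - age_min),
        0.5 * config.lam_floor,
    )

    blocks = _block_assignment(n_reg, config.n_blocks)
    factors = rng.standard_normal((config.n_blocks, n_t))
    global_factor = rng.standard_normal(n_t)
    noise = rng.standard_normal((n_reg, n_t))

    values = lam * factors[blocks] + gam * global_factor + config.noise_sd * noise

    if config.plant_synergy and n_reg >= 3:
        # last region becomes a noisy sum of the first two -> synergy triplet
        values[-1] = (values[0] + values[1] + noise[-1]) / np.sqrt(3.0)

    scanner_idx = int(record.scanner.replace("scanner", "")) if record.scanner else 0
    values = values * (config.scanner_scale**scanner_idx)

    tr = config.sampling_rate_or_tr if config.modality == "fMRI" else None
    rate = config.sampling_rate_or_tr if config.modality == "EEG" else None
    return RegionTimeSeries(
        values=values,
        region_labels=config.region_labels(),
        modality=config.modality,
        tr=tr,
        sampling_rate=rate,
        subject_id=record.subject_id,
    )


def generate_exposome_table(countries: list[str], seed: int = 0) -> pd.DataFrame:
    """Country-level exposome indicators on their conventional scales.

    Columns: GINI (index points, ~25-55), PM25 (ug/m3, ~5-60), communicable
    and non-communicable disease burdens (DALYs per 1e3 population, arbitrary
    but fixed scales), GII (0-1).  LAC-like countries draw from shifted
    distributions so the indicators correlate with region, as in observational
    exposome data.
    """
    if len(countries) < 2:
        raise ValueError("need at least 2 countries")
    rng = np.random.default_rng(seed)
    rows = []
    for c in countries:
        lac = c in _LAC_COUNTRIES
        rows.append(
            {
                "country": c,
                "GINI": rng.uniform(40, 55) if lac else rng.uniform(25, 40),
                "PM25": rng.uniform(15, 60) if lac else rng.uniform(5, 25),
                "communicable_burden": rng.uniform(30, 80) if lac else rng.uniform(5, 30),
                "noncommunicable_burden": rng.uniform(120, 200) if lac else rng.uniform(80, 160),
                "GII": rng.uniform(0.35, 0.6) if lac else rng.uniform(0.05, 0.3),
            }
        )
    return pd.DataFrame(rows)


def simulate_bag_outcomes(
    records: list[CohortRecord],
    exposome: pd.DataFrame,
    *,
    gini_slope: float = 0.0,
    diagnosis_offset: float = 0.0,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject BAG values with documented planted linear effects.

    Expected BAG = gini_slope * (GINI - mean GINI) + diagnosis_offset *
    1[diagnosis != HC] + Gaussian noise.  With both slopes zero, BAG is
    independent of every exposome column.
    """
    rng = np.random.default_rng(seed)
    gini = exposome.set_index("country")["GINI"]
    center = float(gini.mean())
    rows = []
    for rec in records:
        g = float(gini.get(rec.country, center))
        mu = gini_slope * (g - center) + diagnosis_offset * (rec.diagnosis != "HC")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "country": rec.country,
                "diagnosis": rec.diagnosis,
                "sex": rec.sex,
                "region": rec.region,
                "bag": mu + rng.normal(0.0, noise_sd),
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_set(
    records: list[CohortRecord],
    config: CohortConfig,
    out_dir: str | Path,
    *,
    exposome: pd.DataFrame | None = None,
) -> dict:
    """Write per-subject time series, cohort and exposome tables, and a manifest.

    Returns the manifest: one entry per file with path and sha256 checksum.
    Files round-trip bit-exactly through :mod:`braingap.io` readers.
    """
    from . import io as bio

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc

    entries = []
    for k, rec in enumerate(records):
        ts = simulate_subject_timeseries(rec, config, seed=config.seed + 1000 + k)
        path = out / f"{rec.subject_id}_timeseries.tsv"
        bio.write_timeseries_matrix(ts, path)
        entries.append({"path": path.name, "kind": "timeseries", "sha256": _sha256(path)})

    cohort_df = pd.DataFrame([vars(r) for r in records])
    cohort_path = out / "cohort.tsv"
    cohort_df.to_csv(cohort_path, sep="\t", index=False)
    entries.append({"path": cohort_path.name, "kind": "cohort", "sha256": _sha256(cohort_path)})

    if exposome is None:
        countries = sorted({r.country for r in records})
        if len(countries) < 2:
            countries = sorted(set(countries) | {"Chile", "USA"})
        exposome = generate_exposome_table(countries, seed=config.seed)
    expo_path = out / "exposome.tsv"
    exposome.to_csv(expo_path, sep="\t", index=False)
    entries.append({"path": expo_path.name, "kind": "exposome", "sha256": _sha256(expo_path)})

    manifest = {"n_subjects": len(records), "seed": config.seed, "files": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
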
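"""Synthetic asthma cohorts with known ground-truth phenotype labels.

The generator emulates a four-phenotype adult asthma cohort (n = 156) whose
per-phenotype distributions match published per-cluster summary statistics:
normal variables are parameterized by mean and SD; right-skewed biomarkers
(FENO, blood eosinophils, methacholine PC20, sputum eosinophils) are
log-normal, parameterized by geometric mean (GM) and multiplicative
geometric SD (GSD).  Asymmetric summary intervals printed as ``GM +u/-l``
encode the GSD through ``u = GM*(GSD-1)`` and ``l = GM*(1-1/GSD)``.

Each subject keeps a fixed ``truth_cluster`` assigned at baseline; at each
follow-up visit the subject either persists (latent z-scores follow an AR(1)
process) or, with a small switch probability, is re-drawn from a different
phenotype's distributions (its ``current_cluster`` records the source).
Methacholine challenge is not performed when FEV1 %predicted is below 60, so
PC20 is masked for those subject-visits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: the nine clustering variables, in canonical column order
CLUSTERING_VARIABLES = (
    "fev1_pp",      # pre-bronchodilator FEV1, % predicted
    "fvc_pp",       # pre-bronchodilator FVC, % predicted
    "fev1_fvc",     # pre-bronchodilator FEV1/FVC ratio
    "bdr",          # bronchodilator reversibility, % change in FEV1
    "acq7",         # Asthma Control Questionnaire (0-6)
    "aqlq",         # Asthma Quality of Life Questionnaire (1-7)
    "feno",         # fractional exhaled NO, ppb
    "blood_eos",    # blood eosinophils, x1000/uL
    "pc20",         # methacholine PC20, mg/mL
)

#: auxiliary per-subject variables carried alongside the clustering set
EXTRA_VARIABLES = (
    "sputum_eos",   # sputum eosinophils, % of leukocytes
    "sputum_pmn",   # sputum neutrophils, % of leukocytes
    "age",          # years
    "onset_age",    # asthma age of onset, years
    "bmi",          # kg/m2
)

#: physically admissible ranges; draws outside are resampled, not clipped
_VALID_RANGES = {
    "fev1_pp": (10.0, 200.0),
    "fvc_pp": (10.0, 200.0),
    "fev1_fvc": (0.0, 1.2),
    "bdr": (-30.0, 150.0),
    "acq7": (0.0, 6.0),
    "aqlq": (1.0, 7.0),
    "feno": (0.0, math.inf),
    "blood_eos": (0.0, math.inf),
    "pc20": (0.0, math.inf),
    "sputum_eos": (0.0, 100.0),
    "sputum_pmn": (0.0, 100.0),
    "age": (12.0, 100.0),
    "onset_age": (0.0, 90.0),
    "bmi": (12.0, 60.0),
}

ARMS = ("mild", "moderate", "severe")


def geometric_interval(gm: float, gsd: float) -> tuple[float, float]:
    """Asymmetric interval deltas ``(+u, -l)`` of a geometric summary.

    ``upper = gm*gsd - gm`` and ``lower = gm - gm/gsd``; the identity
    ``(gm+u)/gm == gm/(gm-l) == gsd`` holds exactly.
    """
    if gm <= 0:
        raise ValueError(f"geometric mean must be positive, got {gm}")
    if gsd < 1:
        raise ValueError(f"geometric SD must be >= 1, got {gsd}")
    return gm * gsd - gm, gm - gm / gsd


def gsd_from_upper(gm: float, upper: float) -> float:
    """Recover the geometric SD from a printed ``GM +u`` upper delta."""
    if gm <= 0 or upper < 0:
        raise ValueError("need gm > 0 and upper >= 0")
    return (gm + upper) / gm


@dataclass(frozen=True)
class VariableSpec:
    """Distribution of one variable inside one cluster."""

    dist_kind: str            # "normal" | "lognormal"
    location: float           # mean, or geometric mean
    scale: float              # SD, or multiplicative geometric SD

    def __post_init__(self) -> None:
        if self.dist_kind not in ("normal", "lognormal"):
            raise ValueError(f"unknown dist_kind {self.dist_kind!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.dist_kind == "lognormal":
            if self.location <= 0:
                raise ValueError("lognormal location must be positive")
            if self.scale <= 1:
                raise ValueError("geometric SD must exceed 1")

    def from_z(self, z: np.ndarray | float) -> np.ndarray | float:
        """Map standard-normal latent scores to the variable's scale."""
        if self.dist_kind == "normal":
            return self.location + self.scale * np.asarray(z)
        return np.exp(math.log(self.location) + math.log(self.scale) * np.asarray(z))


@dataclass(frozen=True)
class ClusterParams:
    """Per-cluster sample size, variable distributions and arm mixture."""

    cluster_id: str
    n: int
    variables: dict[str, VariableSpec]
    arm_weights: dict[str, float] = field(
        default_factory=lambda: {a: 1 / 3 for a in ARMS}
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cluster size must be >= 1")
        missing = set(CLUSTERING_VARIABLES) - set(self.variables)
        if missing:
            raise ValueError(f"cluster {self.cluster_id}: missing variables {sorted(missing)}")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full description of a synthetic longitudinal cohort."""

    clusters: tuple[ClusterParams, ...]
    visits: tuple[str, ...] = ("baseline", "month_03", "month_06", "month_12")
    within_subject_persistence: float = 0.8
    switch_probability: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.within_subject_persistence <= 1):
            raise ValueError("within_subject_persistence must lie in (0, 1]")
        if not (0 <= self.switch_probability < 1):
            raise ValueError("switch_probability must lie in [0, 1)")
        if len(set(self.visits)) != len(self.visits):
            raise ValueError("visit labels must be unique")


def _nv(mean: float, sd: float) -> VariableSpec:
    return VariableSpec("normal", mean, sd)


def _gv(gm: float, upper: float) -> VariableSpec:
    """Log-normal spec from a printed ``GM +u`` interval."""
    return VariableSpec("lognormal", gm, gsd_from_upper(gm, upper))


# Printed per-cluster summary parameters for the four asthma phenotypes
# (A1 mild/early-onset, A2 eosinophilic/hyper-responsive, A3 neutrophilic/
# obstructive, A4 severe uncontrolled).  Lognormal rows carry GM and the
# upper interval delta from which the GSD is recovered.
_DEFAULT_TABLE: dict[str, dict] = {
    "A1": dict(
        n=28,
        arm={"mild": 0.93, "moderate": 0.07, "severe": 0.0},
        fev1_pp=(103.5, 11.8), fvc_pp=(111.1, 10.8), fev1_fvc=(0.80, 0.08),
        bdr=(10.2, 6.3), acq7=(0.5, 0.5), aqlq=(6.0, 1.0),
        feno=(35.2, 28.1), blood_eos=(0.150, 0.168), pc20=(2.8, 11.3),
        sputum_eos=(1.0, 4.7), sputum_pmn=(41.4, 33.0),
        age=(32.5, 14.3), onset_age=(15.4, 13.9), bmi=(25.2, 3.2),
    ),
    "A2": dict(
        n=44,
        arm={"mild": 0.16, "moderate": 0.52, "severe": 0.32},
        fev1_pp=(77.4, 10.2), fvc_pp=(100.0, 12.0), fev1_fvc=(0.65, 0.08),
        bdr=(17.6, 7.0), acq7=(1.1, 0.5), aqlq=(6.0, 0.6),
        feno=(43.8, 36.7), blood_eos=(0.299, 0.234), pc20=(0.3, 1.4),
        sputum_eos=(7.1, 18.7), sputum_pmn=(42.2, 25.8),
        age=(42.4, 12.0), onset_age=(21.0, 14.0), bmi=(25.7, 3.6),
    ),
    "A3": dict(
        n=49,
        arm={"mild": 0.27, "moderate": 0.43, "severe": 0.30},
        fev1_pp=(76.5, 9.8), fvc_pp=(88.2, 9.8), fev1_fvc=(0.72, 0.08),
        bdr=(14.8, 9.6), acq7=(1.2, 0.5), aqlq=(5.9, 0.8),
        feno=(16.4, 9.7), blood_eos=(0.131, 0.100), pc20=(2.2, 7.0),
        sputum_eos=(0.9, 3.5), sputum_pmn=(63.1, 23.8),
        age=(43.0, 11.8), onset_age=(22.7, 15.2), bmi=(26.9, 3.7),
    ),
    "A4": dict(
        n=35,
        arm={"mild": 0.11, "moderate": 0.26, "severe": 0.63},
        fev1_pp=(66.8, 11.5), fvc_pp=(88.7, 12.0), fev1_fvc=(0.64, 0.11),
        bdr=(32.2, 21.9), acq7=(2.6, 0.9), aqlq=(4.1, 1.1),
        feno=(37.7, 47.8), blood_eos=(0.237, 0.286), pc20=(0.6, 2.8),
        sputum_eos=(3.5, 10.5), sputum_pmn=(55.9, 21.7),
        age=(46.8, 13.3), onset_age=(23.7, 18.6), bmi=(26.6, 4.1),
    ),
}

_LOGNORMAL_VARS = {"feno", "blood_eos", "pc20", "sputum_eos"}


def default_cohort_spec(
    switch_probability: float = 0.10,
    within_subject_persistence: float = 0.8,
    seed: int = 0,
) -> SyntheticCohortSpec:
    """Four-cluster cohort spec with the published per-phenotype parameters.

    Cluster sizes 28/44/49/35 (total 156); FENO, blood eosinophils, PC20 and
    sputum eosinophils are log-normal, the remaining variables normal.
    """
    clusters = []
    for cid, row in _DEFAULT_TABLE.items():
        variables: dict[str, VariableSpec] = {}
        for name in CLUSTERING_VARIABLES + EXTRA_VARIABLES:
            loc, spread = row[name]
            if name in _LOGNORMAL_VARS:
                variables[name] = _gv(loc, spread)
            else:
                variables[name] = _nv(loc, spread)
        total = sum(row["arm"].values())
        arm_weights = {a: w / total for a, w in row["arm"].items()}
        clusters.append(
            ClusterParams(cluster_id=cid, n=row["n"], variables=variables,
                          arm_weights=arm_weights)
        )
    return SyntheticCohortSpec(
        clusters=tuple(clusters),
        switch_probability=switch_probability,
        within_subject_persistence=within_subject_persistence,
        seed=seed,
    )


_MAX_RESAMPLE = 1000


def _draw_in_range(rng: np.random.Generator, var: VariableSpec, name: str,
                   z_prev: float | None, rho: float) -> tuple[float, float]:
    """One AR(1) latent step mapped through the variable spec.

    Draws violating the variable's physical range are resampled (fresh
    innovation) so the within-range distribution shape is preserved.
    """
    lo, hi = _VALID_RANGES[name]
    for _ in range(_MAX_RESAMPLE):
        eps = rng.standard_normal()
        if z_prev is None:
            z = eps
        else:
            z = rho * z_prev + math.sqrt(1 - rho * rho) * eps
        value = float(var.from_z(z))
        if lo <= value <= hi:
            return value, z
    raise RuntimeError(f"could not draw {name} inside {lo}..{hi}")


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Generate one subject-visit row per subject per visit.

    Returns a tidy frame with the nine clustering variables, sputum
    differentials, a squamous-cell QC percentage, demographics, the fixed
    ``truth_cluster`` and the per-visit ``current_cluster``.  PC20 is set
    missing wherever FEV1 %predicted is below 60.  Reproducible: every
    subject owns a seed stream spawned deterministically from the master
    seed, so subsetting subjects does not shift anyone else's draws.
    """
    cluster_by_id = {c.cluster_id: c for c in spec.clusters}
    cluster_ids = list(cluster_by_id)
    rho = spec.within_subject_persistence

    rows = []
    subject_index = 0
    for cl in spec.clusters:
        for _ in range(cl.n):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(subject_index,))
            )
            sid = f"S{subject_index:04d}"
            arm = rng.choice(list(cl.arm_weights), p=list(cl.arm_weights.values()))
            # demographics drawn once at baseline, carried across visits
            demo: dict[str, float] = {}
            for name in ("age", "onset_age", "bmi"):
                demo[name], _ = _draw_in_range(rng, cl.variables[name], name, None, rho)
            if demo["onset_age"] > demo["age"]:
                demo["onset_age"] = demo["age"] * float(rng.uniform(0.2, 0.9))

            z_state: dict[str, float] = {}
            dynamic = [v for v in CLUSTERING_VARIABLES + EXTRA_VARIABLES
                       if v not in ("age", "onset_age", "bmi")]
            for vi, visit in enumerate(spec.visits):
                if vi == 0:
                    current = cl.cluster_id
                elif rng.uniform() < spec.switch_probability:
                    others = [c for c in cluster_ids if c != current]
                    current = others[int(rng.integers(len(others)))]
                source = cluster_by_id[current]
                values: dict[str, float] = {}
                for name in dynamic:
                    prev = z_state.get(name)
                    values[name], z_state[name] = _draw_in_range(
                        rng, source.variables[name], name, prev, rho
                    )
                # squamous-cell contamination of the sputum sample: Beta(2.5, 7.5)
                # scaled to percent; roughly 30% of samples fail the <=30% QC cut
                squamous = float(rng.beta(2.5, 7.5) * 100)
                row = {
                    "subject_id": sid,
                    "visit": visit,
                    "arm": arm,
                    "truth_cluster": cl.cluster_id,
                    "current_cluster": current,
                    "squamous_pct": squamous,
                    **demo,
                    **values,
                }
                if row["fev1_pp"] < 60:
                    row["pc20"] = np.nan  # challenge not performed
                rows.append(row)
            subject_index += 1

    columns = (
        ["subject_id", "visit", "arm"]
        + list(CLUSTERING_VARIABLES)
        + ["sputum_eos", "sputum_pmn", "squamous_pct"]
        + ["age", "onset_age", "bmi", "truth_cluster", "current_cluster"]
    )
    return pd.DataFrame(rows)[columns]


# ---------------------------------------------------------------------------
# serialization

def spec_to_yaml(spec: SyntheticCohortSpec, path) -> None:
    doc = {
        "seed": spec.seed,
        "visits": list(spec.visits),
        "within_subject_persistence": spec.within_subject_persistence,
        "switch_probability": spec.switch_probability,
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "n": c.n,
                "arm_weights": dict(c.arm_weights),
                "variables": {
                    name: {"dist_kind": v.dist_kind, "location": v.location,
                           "scale": v.scale}
                    for name, v in c.variables.items()
                },
            }
            for c in spec.clusters
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path) -> SyntheticCohortSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    clusters = tuple(
        ClusterParams(
            cluster_id=c["cluster_id"],
            n=int(c["n"]),
            arm_weights={k: float(v) for k, v in c["arm_weights"].items()},
            variables={
                name: VariableSpec(v["dist_kind"], float(v["location"]), float(v["scale"]))
                for name, v in c["variables"].items()
            },
        )
        for c in doc["clusters"]
    )
    return SyntheticCohortSpec(
        clusters=clusters,
        visits=tuple(doc["visits"]),
        within_subject_persistence=float(doc["within_subject_persistence"]),
        switch_probability=float(doc["switch_probability"]),
        seed=int(doc["seed"]),
    )


def write_cohort_csv(records: pd.DataFrame, path) -> None:
    """Tidy CSV, one row per subject-visit, empty cell = missing."""
    records.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
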
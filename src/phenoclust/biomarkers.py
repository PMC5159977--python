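"""Rule-based inflammatory phenotype calling and transcriptomic support.

Sputum granulocyte classes partition the (eosinophil %, neutrophil %)
plane at 3% eosinophils and 60% neutrophils: paucigranulocytic,
neutrophilic, eosinophilic, or mixed.  Simple biomarker highs use
FENO >= 35 ppb and blood eosinophils >= 300/uL (inclusive cuts).

Transcriptomic support covers: the limit of reliable quantification (LOD)
for log2 microarray intensities, estimated from the 90th percentile of
nonspecific-probe signal and from the inflection of a smoothed SD-vs-mean
curve; the quantifiable-probe filter (mean above threshold in at least one
cohort); a rank-based single-sample signature enrichment score; and the
type-2-high call, flagging subjects whose indicator (e.g. CCL26 expression
or an IL-13 signature enrichment score) lies beyond the 95th percentile of
the healthy-control distribution.

The enrichment score is a mean-normalized-rank statistic, not a
reimplementation of kernel-based GSVA: genes are ranked within each
sample, and the score is twice the difference between the mean normalized
rank of signature genes and 0.5, so it lives in [-1, 1], is positive for
coordinate up-expression, and is invariant under any monotone per-sample
transformation — the only properties the downstream percentile dichotomy
uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

GRANULOCYTE_CLASSES = ("paucigranulocytic", "neutrophilic", "mixed", "eosinophilic")

#: inclusive decision thresholds
SPUTUM_EOS_CUT = 3.0     # % of leukocytes
SPUTUM_PMN_CUT = 60.0    # % of leukocytes
FENO_CUT = 35.0          # ppb
BLOOD_EOS_CUT = 300.0    # cells/uL


def granulocyte_class(eos_pct: float, pmn_pct: float) -> str | None:
    """Sputum granulocyte class from eosinophil and neutrophil percentages.

    Returns None when either input is missing.  Boundaries are inclusive:
    eos >= 3% counts as eosinophil-high, pmn >= 60% as neutrophil-high.
    """
    if eos_pct is None or pmn_pct is None:
        return None
    if not (np.isfinite(eos_pct) and np.isfinite(pmn_pct)):
        return None
    eos_high = eos_pct >= SPUTUM_EOS_CUT
    pmn_high = pmn_pct >= SPUTUM_PMN_CUT
    if eos_high and pmn_high:
        return "mixed"
    if eos_high:
        return "eosinophilic"
    if pmn_high:
        return "neutrophilic"
    return "paucigranulocytic"


def threshold_flags(feno: float, blood_eos: float) -> dict[str, bool | None]:
    """FENO-high / blood-eosinophil-high / either-high indicator flags.

    ``blood_eos`` is in cells/uL.  A missing input yields None for its flag;
    ``either_high`` is None only when both are missing (OR over observed).
    """
    feno_ok = feno is not None and np.isfinite(feno)
    eos_ok = blood_eos is not None and np.isfinite(blood_eos)
    feno_high = bool(feno >= FENO_CUT) if feno_ok else None
    eos_high = bool(blood_eos >= BLOOD_EOS_CUT) if eos_ok else None
    if feno_high is None and eos_high is None:
        either = None
    else:
        either = bool(feno_high or eos_high)
    return {"feno_high": feno_high, "eos_high": eos_high, "either_high": either}


def call_biomarkers(records: pd.DataFrame) -> pd.DataFrame:
    """Append granulocyte class and threshold flags to a cohort table.

    Expects ``sputum_eos``/``sputum_pmn`` in % of leukocytes, ``feno`` in
    ppb and ``blood_eos`` in x1000 cells/uL (the cohort unit; converted to
    cells/uL for the 300/uL cut).
    """
    out = records.copy()
    out["granulocyte_class"] = [
        granulocyte_class(e, p)
        for e, p in zip(out["sputum_eos"], out["sputum_pmn"])
    ]
    flags = [
        threshold_flags(f, b * 1000.0 if np.isfinite(b) else np.nan)
        for f, b in zip(out["feno"].astype(float), out["blood_eos"].astype(float))
    ]
    for key in ("feno_high", "eos_high", "either_high"):
        out[key] = [fl[key] for fl in flags]
    return out


# ---------------------------------------------------------------------------
# expression support

@dataclass
class ExpressionMatrix:
    """log2 expression, genes/probes x samples, with cohort labels."""

    values: pd.DataFrame                 # index = probe/gene, columns = sample
    cohorts: pd.Series                   # sample -> cohort label
    nonspecific: pd.Series | None = None  # probe -> bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if len(self.cohorts) != self.values.shape[1]:
            raise ValueError("one cohort label per sample required")


@dataclass(frozen=True)
class LodResult:
    percentile_threshold: float | None   # rule (a)
    variance_threshold: float            # rule (b)
    consensus: float


def lod_threshold(
    em: ExpressionMatrix,
    min_nonspecific: int = 50,
    smooth_window: int = 101,
    override: float | None = None,
) -> LodResult:
    """Limit of reliable quantification for log2 intensities.

    Rule (a): 90th percentile of the nonspecific probes' mean intensities.
    Rule (b): the mean intensity at which a moving-average smoothed
    SD-vs-mean curve across all probes attains its maximum (variance
    inflates as signal decays into background).  The consensus is the max
    of the two; an explicit ``override`` (e.g. a platform-specific constant
    such as 5.5 or 4.75) short-circuits both.
    """
    means = em.values.mean(axis=1).to_numpy()
    sds = em.values.std(axis=1, ddof=1).to_numpy()

    if override is not None:
        return LodResult(percentile_threshold=None, variance_threshold=float("nan"),
                         consensus=float(override))

    if em.nonspecific is not None and int(em.nonspecific.sum()) >= min_nonspecific:
        ns_means = em.values.loc[em.nonspecific[em.nonspecific].index].mean(axis=1)
        perc = float(np.quantile(ns_means.to_numpy(), 0.90))
    else:
        if em.nonspecific is not None and em.nonspecific.sum() > 0:
            warnings.warn("too few nonspecific probes; percentile rule skipped",
                          stacklevel=2)
            perc = None
        else:
            raise ValueError("no nonspecific probes flagged; percentile rule unavailable")

    order = np.argsort(means)
    w = min(smooth_window, len(order))
    kernel = np.ones(w) / w
    smoothed = np.convolve(sds[order], kernel, mode="same")
    var_thr = float(means[order][int(np.argmax(smoothed))])

    candidates = [t for t in (perc, var_thr) if t is not None]
    return LodResult(percentile_threshold=perc, variance_threshold=var_thr,
                     consensus=float(max(candidates)))


def quantifiable_filter(
    em: ExpressionMatrix,
    threshold: float,
    cohorts: list[str] | None = None,
) -> pd.Index:
    """Probes whose per-cohort mean exceeds the threshold in >= 1 cohort."""
    labels = cohorts if cohorts is not None else sorted(em.cohorts.unique())
    keep = np.zeros(em.values.shape[0], dtype=bool)
    for cohort in labels:
        cols = em.cohorts.index[em.cohorts == cohort]
        if len(cols) == 0:
            continue
        keep |= em.values[cols].mean(axis=1).to_numpy() > threshold
    return em.values.index[keep]


def signature_enrichment(
    em: ExpressionMatrix | pd.DataFrame,
    gene_set: list[str],
    min_genes: int = 5,
) -> pd.Series:
    """Per-sample rank-based enrichment score of a gene signature.

    Genes are ranked within each sample (average ranks for ties); the score
    is ``2 * (mean((rank - 0.5)/N over signature genes) - 0.5)``, in
    [-1, 1].  When signature genes occupy the top |S| ranks the score is
    exactly ``(N - |S|)/N``.
    """
    values = em.values if isinstance(em, ExpressionMatrix) else em
    present = [g for g in gene_set if g in values.index]
    if len(present) < min_genes:
        raise ValueError(
            f"only {len(present)} signature gene(s) present; need >= {min_genes}"
        )
    N = values.shape[0]
    scores = {}
    for sample in values.columns:
        ranks = rankdata(values[sample].to_numpy())
        norm = (ranks - 0.5) / N
        idx = values.index.get_indexer(present)
        scores[sample] = float(2.0 * (norm[idx].mean() - 0.5))
    return pd.Series(scores, name="enrichment_score")


def read_gmt(path) -> dict[str, list[str]]:
    """Gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# type-2 phenotype calls

@dataclass
class T2Call:
    """Per-subject type-2-high dichotomy against a healthy reference."""

    values: pd.Series
    threshold: float
    high: pd.Series                      # value strictly beyond threshold
    rule: str = "percentile"


def t2_call(
    values: pd.Series | np.ndarray,
    healthy_values: np.ndarray,
    rule: str = "percentile",
    q: float = 0.95,
) -> T2Call:
    """Flag subjects whose indicator lies beyond the healthy distribution.

    ``rule="percentile"`` (default) cuts at the empirical q-quantile of the
    healthy values (linear interpolation between order statistics);
    ``rule="max"`` cuts at the healthy maximum.  "Beyond" is strict: a
    value exactly at the threshold is called low.
    """
    healthy = np.asarray(healthy_values, dtype=float)
    healthy = healthy[np.isfinite(healthy)]
    if healthy.size < 10:
        raise ValueError("need at least 10 healthy reference values")
    if rule == "percentile":
        threshold = float(np.quantile(healthy, q))
    elif rule == "max":
        threshold = float(healthy.max())
    else:
        raise ValueError(f"unknown rule {rule!r}")
    series = values if isinstance(values, pd.Series) else pd.Series(np.asarray(values))
    return T2Call(values=series, threshold=threshold,
                  high=series > threshold, rule=rule)
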
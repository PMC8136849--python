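"""Model interpretation and evaluation utilities.

Covers gradient-based contribution scores (gradient x input and raw
gradient), in-silico saturation mutagenesis, the paired-bootstrap
model-comparison procedure, and the preprocessing formulas used for
endogenous translation measurements (Ribo-Seq translation efficiency,
replicate-filtered Trip-Seq expression, median protein-to-mRNA ratio) as
pure functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seq_core import ALPHABET, NucSequence, as_sequence, encode_batch

__all__ = [
    "ContributionMatrix",
    "SaturationResult",
    "ComparisonResult",
    "gradient_contributions",
    "saturation_mutagenesis",
    "bootstrap_compare",
    "translation_efficiency",
    "preprocess_expression",
]


@dataclass(frozen=True)
class ContributionMatrix:
    """L x 4 per-base contribution scores aligned to the one-hot input."""

    values: np.ndarray
    flavor: str  # "gradient_x_input" or "raw_gradient"

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError("values must be L x 4")

    def to_frame(self, sequence=None) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(ALPHABET))
        if sequence is not None:
            df.insert(0, "base", list(as_sequence(sequence).bases))
        return df


def gradient_contributions(
    model, seq: "NucSequence | str", flavor: str = "gradient_x_input", library=None
) -> ContributionMatrix:
    """Exact input gradient of the scalar MRL prediction.

    ``gradient_x_input`` multiplies the gradient elementwise with the
    one-hot input (zero off-sequence channels); ``raw_gradient`` returns
    the gradient itself, suitable as hypothetical contribution scores.
    Requires a differentiable model (the simulator oracle is not one).
    """
    if flavor not in ("gradient_x_input", "raw_gradient"):
        raise ValueError(f"unknown flavor {flavor!r}")
    if not hasattr(model, "input_gradient"):
        raise TypeError(
            f"{type(model).__name__} is not differentiable; gradient "
            "contributions need a neural model"
        )
    batch = encode_batch([seq], dtype=getattr(model, "dtype", np.float64))
    grad = model.input_gradient(batch, library=library)[0].astype(np.float64)
    if flavor == "gradient_x_input":
        grad = grad * batch.values[0].astype(np.float64)
    return ContributionMatrix(values=grad, flavor=flavor)


@dataclass(frozen=True)
class SaturationResult:
    """All-SNV in-silico mutagenesis of one sequence.

    ``log2fc[i, j]`` is the log2 MRL fold change of mutating position ``i``
    to its j-th alternative base (alphabet order, reference base excluded);
    ``mean_abs_log2fc[i]`` averages the absolute values of the three
    alternatives, the per-position expected mutation impact.
    """

    sequence: NucSequence
    alt_bases: tuple  # per position: the 3 alternative bases
    log2fc: np.ndarray  # (L, 3)
    mean_abs_log2fc: np.ndarray  # (L,)
    mrl_ref: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (ref, alts) in enumerate(zip(self.sequence.bases, self.alt_bases)):
            for j, alt in enumerate(alts):
                rows.append(
                    {"position": i, "ref": ref, "alt": alt,
                     "log2fc": self.log2fc[i, j],
                     "mean_abs_log2fc": self.mean_abs_log2fc[i]}
                )
        return pd.DataFrame(rows)


def saturation_mutagenesis(
    predictor, seq: "NucSequence | str", library=None
) -> SaturationResult:
    """Score all 3L single-base substitutions as log2(pred_mut / pred_ref).

    Works with any positive-valued predictor (trained model or simulator
    oracle).  Ambiguous (N) positions are not supported.
    """
    seq = as_sequence(seq)
    if "N" in seq.bases:
        raise ValueError("saturation mutagenesis requires an unambiguous sequence")
    L = len(seq)
    alt_bases = tuple(
        tuple(b for b in ALPHABET if b != ref) for ref in seq.bases
    )
    mutants = [
        seq.bases[:i] + alt + seq.bases[i + 1 :]
        for i in range(L)
        for alt in alt_bases[i]
    ]
    preds = np.asarray(
        predictor.predict_sequences([seq.bases] + mutants, library=library),
        dtype=np.float64,
    )
    if np.any(preds <= 0):
        raise ValueError("non-positive MRL prediction; log2 fold change undefined")
    ref_pred = preds[0]
    log2fc = np.log2(preds[1:] / ref_pred).reshape(L, 3)
    return SaturationResult(
        sequence=seq,
        alt_bases=alt_bases,
        log2fc=log2fc,
        mean_abs_log2fc=np.abs(log2fc).mean(axis=1),
        mrl_ref=float(ref_pred),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Paired-bootstrap comparison of two predictors against observations.

    ``ci_halfwidth = multiplier * sd_diff`` (standard deviations, not
    standard errors, of the bootstrap-replicate correlation differences);
    the difference is significant when the interval excludes zero.
    """

    metric_a: float
    metric_b: float
    mean_diff: float
    sd_diff: float
    multiplier: float
    ci_halfwidth: float
    significant: bool
    n_boot: int
    method: str


def _corr(x, y, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y)[0])
    if method == "spearman":
        return float(stats.spearmanr(x, y)[0])
    raise ValueError(f"unknown method {method!r}")


def bootstrap_compare(
    pred_a,
    pred_b,
    observed,
    n_boot: int = 100,
    multiplier: float = 3.54,
    seed: int = 0,
    method: str = "pearson",
) -> ComparisonResult:
    """Bootstrap the difference corr(pred_a, obs) - corr(pred_b, obs).

    Triples (pred_a_i, pred_b_i, obs_i) are resampled jointly so both
    models are compared on identical resamples.  The default interval
    half-width of 3.54 standard deviations corresponds to a 95% confidence
    level with a Bonferroni correction over 24 comparisons.
    """
    pred_a = np.asarray(pred_a, dtype=np.float64)
    pred_b = np.asarray(pred_b, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    n = observed.shape[0]
    if pred_a.shape != (n,) or pred_b.shape != (n,):
        raise ValueError("pred_a, pred_b and observed must have equal length")
    if n < 10:
        raise ValueError("need at least 10 observations")
    for name, v in (("pred_a", pred_a), ("pred_b", pred_b), ("observed", observed)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant; correlation undefined")
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        obs = observed[idx]
        if np.ptp(obs) == 0 or np.ptp(pred_a[idx]) == 0 or np.ptp(pred_b[idx]) == 0:
            diffs[b] = np.nan  # degenerate resample
            continue
        diffs[b] = _corr(pred_a[idx], obs, method) - _corr(pred_b[idx], obs, method)
    diffs = diffs[np.isfinite(diffs)]
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    ci_halfwidth = multiplier * sd_diff
    significant = bool(abs(mean_diff) - ci_halfwidth > 0)
    return ComparisonResult(
        metric_a=_corr(pred_a, observed, method),
        metric_b=_corr(pred_b, observed, method),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        multiplier=multiplier,
        ci_halfwidth=ci_halfwidth,
        significant=significant,
        n_boot=n_boot,
        method=method,
    )


def translation_efficiency(rpf_counts, rna_counts, min_rpf: int = 10):
    """TE = RPF / RNA per gene, with low-coverage exclusion.

    Genes with fewer than ``min_rpf`` ribosome-protected-fragment reads, or
    zero RNA-seq reads, are excluded (TE set to NaN).  Returns
    ``(te, excluded)`` where ``excluded`` is a boolean mask.
    """
    rpf = np.asarray(rpf_counts, dtype=np.float64)
    rna = np.asarray(rna_counts, dtype=np.float64)
    if rpf.shape != rna.shape:
        raise ValueError("rpf_counts and rna_counts must have equal length")
    if np.any(rpf < 0) or np.any(rna < 0):
        raise ValueError("counts must be non-negative")
    excluded = (rpf < min_rpf) | (rna <= 0)
    te = np.full(rpf.shape, np.nan)
    ok = ~excluded
    te[ok] = rpf[ok] / rna[ok]
    return te, excluded


def preprocess_expression(replicate_values, tpm_min: float = 1.0, mode: str = "tripseq"):
    """Collapse per-replicate (or per-tissue) expression to one value per row.

    ``tripseq``: rows with any replicate below ``tpm_min`` are excluded,
    remaining rows are replicate-averaged.  ``ptr``: row median ignoring
    missing values; rows with no finite value are excluded.  Returns
    ``(values, excluded)``.
    """
    vals = np.asarray(replicate_values, dtype=np.float64)
    if vals.ndim == 1:
        vals = vals[:, None]
    if mode == "tripseq":
        excluded = np.any(np.nan_to_num(vals, nan=-np.inf) < tpm_min, axis=1)
        out = np.full(vals.shape[0], np.nan)
        out[~excluded] = vals[~excluded].mean(axis=1)
        return out, excluded
    if mode == "ptr":
        excluded = ~np.any(np.isfinite(vals), axis=1)
        out = np.full(vals.shape[0], np.nan)
        with np.errstate(all="ignore"):
            out[~excluded] = np.nanmedian(vals[~excluded], axis=1)
        return out, excluded
    raise ValueError(f"unknown mode {mode!r}")
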
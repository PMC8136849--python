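"""In-silico scoring of upstream TIS context strength.

A model that only outputs MRL does not rate start-codon contexts directly,
but it can be forced to: embed a codon-plus-context window out of frame in
random background sequences of length equal to the model's receptive field,
predict MRL once with the codon active and once with it deactivated (AGG),
and average the fold change over many seeded backgrounds.  Strong contexts
repress MRL more (the out-of-frame start captures more scanning ribosomes),
so predicted fold changes are expected to correlate *negatively* with
measured context strengths.

Context window conventions: AUG contexts use the -6..+5 window (6 nt
upstream flank, 2 nt downstream); alternative start codons use -3..+4
(3 nt upstream, 1 nt downstream).  Contexts that inadvertently contain a
second AUG (e.g. AAUGGGAUGGG) are excluded — the effective start would be
ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seq_core import as_sequence, frame_index

__all__ = [
    "TISContext",
    "DEACTIVATED_CODON",
    "has_unintended_aug",
    "predicted_tis_effect",
    "tis_benchmark",
    "read_context_table",
]

DEACTIVATED_CODON = "AGG"

# (upstream flank, downstream flank) lengths per codon class
_AUG_FLANKS = (6, 2)  # -6..+5 window
_ALT_FLANKS = (3, 1)  # -3..+4 window


@dataclass(frozen=True)
class TISContext:
    """A start codon with its flanking context and an optional measured
    relative initiation strength."""

    codon: str
    upstream: str
    downstream: str
    measured_strength: float | None = None

    def __post_init__(self):
        codon = as_sequence(self.codon).bases
        up = as_sequence(self.upstream).bases if self.upstream else ""
        down = as_sequence(self.downstream).bases if self.downstream else ""
        object.__setattr__(self, "codon", codon)
        object.__setattr__(self, "upstream", up)
        object.__setattr__(self, "downstream", down)
        want = _AUG_FLANKS if codon == "AUG" else _ALT_FLANKS
        if (len(up), len(down)) != want:
            raise ValueError(
                f"{codon} context needs flank lengths {want}, "
                f"got ({len(up)}, {len(down)})"
            )

    def assemble(self, active: bool = True) -> str:
        return self.upstream + (self.codon if active else DEACTIVATED_CODON) + self.downstream

    @property
    def window_length(self) -> int:
        return len(self.upstream) + 3 + len(self.downstream)


def has_unintended_aug(context: TISContext, active: bool = True) -> bool:
    """True iff the assembled window contains an AUG other than the central
    codon (for AUG contexts) or any AUG at all (for non-AUG codons)."""
    window = context.assemble(active=active)
    central = len(context.upstream)
    for i in range(len(window) - 2):
        if window[i : i + 3] == "AUG":
            if context.codon == "AUG" and active and i == central:
                continue
            return True
    return False


def _codon_placement(total_length: int, context: TISContext) -> int:
    """Deterministic out-of-frame placement: codon start position with
    frame_index == 1 (+1 frame), window fully inside, closest to center."""
    up = len(context.upstream)
    down = len(context.downstream)
    candidates = [
        i
        for i in range(up, total_length - 2 - down)
        if frame_index(i, total_length) == 1
    ]
    if not candidates:
        raise ValueError(
            f"receptive field {total_length} too small for a "
            f"{context.window_length} nt context window"
        )
    center = (total_length - 3) / 2
    return min(candidates, key=lambda i: (abs(i - center), i))


def _model_length(predictor, total_length):
    if total_length is not None:
        return int(total_length)
    config = getattr(predictor, "config", None)
    if config is not None:
        from .model_zoo import receptive_field

        return receptive_field(config)
    return 19  # receptive field of the main frame-pooling architecture


def predicted_tis_effect(
    predictor,
    context: TISContext,
    n_backgrounds: int = 100,
    seed: int = 0,
    total_length: int | None = None,
    average: str = "plain",
    library=None,
) -> float:
    """Mean predicted MRL fold change (active / deactivated) over seeded
    random backgrounds.

    The context is embedded at a fixed out-of-frame position in uniform
    random backgrounds of ``total_length`` (default: the predictor's
    receptive field).  ``average="plain"`` returns the mean fold change;
    ``"log2"`` returns the mean log2 fold change.
    """
    if has_unintended_aug(context, active=True) or has_unintended_aug(context, active=False):
        raise ValueError("context contains an unintended AUG; excluded from scoring")
    if average not in ("plain", "log2"):
        raise ValueError("average must be 'plain' or 'log2'")
    L = _model_length(predictor, total_length)
    pos = _codon_placement(L, context)
    win_start = pos - len(context.upstream)
    active = context.assemble(True)
    inactive = context.assemble(False)
    rng = np.random.default_rng(seed)
    base_arr = np.array(list("ACGU"))
    act_seqs, inact_seqs = [], []
    for _ in range(n_backgrounds):
        bg = "".join(rng.choice(base_arr, size=L))
        act_seqs.append(bg[:win_start] + active + bg[win_start + len(active):])
        inact_seqs.append(bg[:win_start] + inactive + bg[win_start + len(inactive):])
    p_act = predictor.predict_sequences(act_seqs, library=library)
    p_inact = predictor.predict_sequences(inact_seqs, library=library)
    fold = np.asarray(p_act, dtype=float) / np.asarray(p_inact, dtype=float)
    return float(np.mean(np.log2(fold)) if average == "log2" else np.mean(fold))


def tis_benchmark(
    predictor,
    contexts,
    n_backgrounds: int = 100,
    seed: int = 0,
    total_length: int | None = None,
    average: str = "plain",
    library=None,
):
    """Score every context and correlate predictions with measurements.

    Returns ``(summary dict, per-context DataFrame)``.  Filtered contexts
    (unintended AUG, window too large) appear in the table with the filter
    reason and are excluded from the correlations.  With fewer than 3
    scored measured contexts, or constant measurements, the correlations
    are reported as NaN with a reason.
    """
    rows = []
    for ctx in contexts:
        row = {
            "codon": ctx.codon,
            "upstream": ctx.upstream,
            "downstream": ctx.downstream,
            "measured_strength": ctx.measured_strength,
            "predicted_effect": np.nan,
            "filtered_reason": "",
        }
        try:
            row["predicted_effect"] = predicted_tis_effect(
                predictor, ctx, n_backgrounds=n_backgrounds,
                seed=seed,  # shared backgrounds: paired design across contexts
                total_length=total_length, average=average, library=library,
            )
        except ValueError as exc:
            row["filtered_reason"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    kept = table[
        (table["filtered_reason"] == "") & table["measured_strength"].notna()
    ]
    summary = {
        "n_contexts": len(table),
        "n_scored": int((table["filtered_reason"] == "").sum()),
        "n_correlated": len(kept),
        "pearson": np.nan,
        "spearman": np.nan,
        "note": "",
    }
    if len(kept) < 3:
        if summary["n_scored"] == 0:
            raise ValueError("all contexts were filtered; nothing to benchmark")
        summary["note"] = "fewer than 3 measured contexts; correlations undefined"
    elif kept["measured_strength"].nunique() < 2 or kept["predicted_effect"].nunique() < 2:
        summary["note"] = "constant values; correlations undefined"
    else:
        summary["pearson"] = float(
            stats.pearsonr(kept["predicted_effect"], kept["measured_strength"])[0]
        )
        summary["spearman"] = float(
            stats.spearmanr(kept["predicted_effect"], kept["measured_strength"])[0]
        )
    return summary, table


def read_context_table(path) -> list[TISContext]:
    """Read a context CSV with columns codon, upstream, downstream, strength."""
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        strength = r.get("strength")
        out.append(
            TISContext(
                codon=str(r["codon"]),
                upstream=str(r["upstream"]),
                downstream=str(r["downstream"]),
                measured_strength=None if pd.isna(strength) else float(strength),
            )
        )
    return out
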
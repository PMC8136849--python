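"""Leaky-scanning MRL simulator producing MPRA-like training data.

The simulator emulates libraries of random 5'UTR sequences with mean
ribosome load (MRL) labels, generated by an explicit leaky-scanning model:
a ribosome scans 5'->3'; at every candidate upstream translation initiation
site (uTIS: AUG, CUG or GUG) it initiates with a probability that increases
with the Kozak-like context score and the intrinsic codon strength,
otherwise it scans on.  Initiation at a uORF (a uTIS with an in-frame stop
codon before the canonical start) either terminates and drops off
(contributing a low load ``mu_uorf``) or reinitiates with probability
``reinit_prob``; initiation at a non-uORF uTIS commits the ribosome to that
start: in frame with the canonical CDS it merely extends the N terminus
(full load ``mu_main``), out of frame it produces an aberrant product (low
load ``mu_oof``).  Mass reaching the canonical start contributes
``mu_main``.  The noise-free expectation over these outcomes is the
simulator's oracle MRL; datasets add Gaussian noise and an optional
per-library affine output scaling.

This is a structural model, not a biophysically calibrated one: it gives
random sequences exactly the frame-dependent uTIS/uORF signal that
frame-aware architectures are designed to exploit, with analytically known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq_core import NucSequence, as_sequence, frame_index
from .training import MRLDataset

__all__ = [
    "ScanningParams",
    "DEFAULT_PARAMS",
    "UTISCandidate",
    "AnnotatedUTR",
    "scan_annotate",
    "oracle_mrl",
    "OraclePredictor",
    "simulate_dataset",
    "mrl_from_polysome_fractions",
]

START_CODONS = ("AUG", "CUG", "GUG")
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

# Kozak-like context window: positions -6..-1, the codon itself (+1..+3,
# zero rows; codon identity is scored separately), and +4..+5.
_PWM_OFFSETS = list(range(-6, 0)) + [0, 1, 2] + [3, 4]


def _default_kozak_pwm() -> np.ndarray:
    """Log-odds-style weights; the -3 purine and +4 G dominate (Kozak
    consensus GCC(A/G)CCAUGG)."""
    pwm = np.zeros((11, 4))
    # rows: 0..5 = -6..-1, 6..8 = codon, 9..10 = +4..+5; cols A,C,G,U
    pwm[3] = [2.0, -0.5, 1.5, -0.5]  # -3: A > G >> C/U
    pwm[9] = [0.0, -0.25, 1.0, -0.25]  # +4: G favoured
    pwm[4] = [0.2, 0.0, 0.2, -0.2]  # -2: mild
    pwm[5] = [0.0, 0.2, 0.0, -0.2]  # -1: mild
    return pwm


@dataclass(frozen=True)
class ScanningParams:
    """Parameters of the leaky-scanning model.

    ``p_init = clip(logistic(init_slope * context_score + init_intercept)
    * codon_strength, 0, 1)``.  Default mean loads order
    ``mu_main > mu_oof > mu_uorf > 0``.
    """

    kozak_pwm: np.ndarray = field(default_factory=_default_kozak_pwm)
    codon_strength: tuple = (("AUG", 1.0), ("CUG", 0.3), ("GUG", 0.15))
    init_slope: float = 1.0
    init_intercept: float = -1.0
    reinit_prob: float = 0.5
    mu_main: float = 6.0
    mu_uorf: float = 1.0
    mu_oof: float = 2.0
    noise_sd: float = 0.3
    library_affines: tuple = ((1.0, 0.0),)

    def __post_init__(self):
        if np.asarray(self.kozak_pwm).shape != (11, 4):
            raise ValueError("kozak_pwm must be 11 x 4 (-6..+5 window)")
        if not 0 <= self.reinit_prob <= 1:
            raise ValueError("reinit_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def codon_strength_map(self) -> dict:
        return dict(self.codon_strength)

    def init_probability(self, context_score: float, codon: str) -> float:
        strength = self.codon_strength_map.get(codon, 0.0)
        p = strength / (1.0 + np.exp(-(self.init_slope * context_score + self.init_intercept)))
        return float(np.clip(p, 0.0, 1.0))


DEFAULT_PARAMS = ScanningParams()

_BASE_COL = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class UTISCandidate:
    """One candidate upstream start codon."""

    position: int  # 0-based start of the codon
    codon: str
    frame: int  # frame_index(position, L); 0 = in frame with the CDS
    context_score: float
    is_uorf: bool  # has an in-frame stop codon strictly before the CDS


@dataclass(frozen=True)
class AnnotatedUTR:
    """Per-sequence uTIS annotation, candidates listed 5'->3'."""

    sequence: NucSequence
    candidates: tuple


def _context_score(bases: str, pos: int, pwm: np.ndarray) -> float:
    """Sum PWM weights over the -6..+5 window; missing flanks and N score 0."""
    L = len(bases)
    score = 0.0
    for row, off in enumerate(_PWM_OFFSETS):
        i = pos + off
        if 0 <= i < L:
            col = _BASE_COL.get(bases[i])
            if col is not None:
                score += pwm[row, col]
    return score


def scan_annotate(
    seq: "NucSequence | str", params: ScanningParams = DEFAULT_PARAMS
) -> AnnotatedUTR:
    """Annotate every AUG/CUG/GUG occurrence with frame, context and uORF
    status.  Stop codons are scanned in the uTIS's own frame, fully within
    the sequence (strictly before the canonical start)."""
    seq = as_sequence(seq)
    bases = seq.bases
    L = len(bases)
    if L < 3:
        raise ValueError("sequence must be >= 3 nt")
    pwm = np.asarray(params.kozak_pwm)
    cands = []
    for i in range(L - 2):
        codon = bases[i : i + 3]
        if codon not in START_CODONS:
            continue
        is_uorf = False
        q = i + 3
        while q + 3 <= L:
            if bases[q : q + 3] in STOP_CODONS:
                is_uorf = True
                break
            q += 3
        cands.append(
            UTISCandidate(
                position=i,
                codon=codon,
                frame=frame_index(i, L),
                context_score=_context_score(bases, i, pwm),
                is_uorf=is_uorf,
            )
        )
    return AnnotatedUTR(sequence=seq, candidates=tuple(cands))


def oracle_mrl(
    seq: "NucSequence | str",
    params: ScanningParams = DEFAULT_PARAMS,
    frame_shift: int = 0,
) -> float:
    """Noise-free expected MRL under the sequential leaky-scanning model.

    The scanning mass is followed 5'->3' through every candidate uTIS.  A
    uORF absorbs initiating mass with probability ``1 - reinit_prob``
    (load ``mu_uorf``); a non-uORF uTIS absorbs all initiating mass, at load
    ``mu_main`` when in frame (N-terminal extension) or ``mu_oof`` when out
    of frame; residual mass initiates at the canonical start (``mu_main``).

    ``frame_shift`` evaluates frames as if ``frame_shift`` masked positions
    were appended at the 3' end (the simulated-frameshift device); appended
    padding contains no bases, so only the frame classes change.
    """
    ann = scan_annotate(seq, params)
    L = len(ann.sequence)
    residual = 1.0
    total = 0.0
    r = params.reinit_prob
    for cand in ann.candidates:
        p = params.init_probability(cand.context_score, cand.codon)
        if cand.is_uorf:
            dropped = residual * p * (1.0 - r)
            total += dropped * params.mu_uorf
            residual -= dropped
        else:
            absorbed = residual * p
            in_frame = (L + frame_shift - cand.position) % 3 == 0
            total += absorbed * (params.mu_main if in_frame else params.mu_oof)
            residual -= absorbed
    return total + residual * params.mu_main


class OraclePredictor:
    """The simulator's noise-free oracle wrapped as a predictor.

    Exposes the same ``predict_sequences(seqs, library=None, frame_shift=0)``
    surface as a trained model, so downstream pipelines (variant scoring,
    TIS benchmarking, saturation mutagenesis) can be tested against exact
    expected values without trained weights.  ``library`` applies the
    corresponding affine from ``params.library_affines``; ``None`` returns
    the raw oracle scale.
    """

    def __init__(self, params: ScanningParams = DEFAULT_PARAMS):
        self.params = params

    def predict_sequences(self, seqs, library=None, frame_shift: int = 0) -> np.ndarray:
        vals = np.array(
            [oracle_mrl(s, self.params, frame_shift=frame_shift) for s in seqs]
        )
        if library is not None:
            scale, bias = self.params.library_affines[int(library)]
            vals = scale * vals + bias
        return vals


def simulate_dataset(
    n: int,
    length_spec,
    params: ScanningParams = DEFAULT_PARAMS,
    library: int = 0,
    seed: int = 0,
) -> MRLDataset:
    """Simulate an MPRA-like library of i.i.d. uniform-base random 5'UTRs.

    ``length_spec`` is a fixed length (int) or an inclusive ``(lo, hi)``
    range sampled uniformly.  Labels are
    ``scale * (oracle_mrl + N(0, noise_sd)) + bias`` with the affine taken
    from ``params.library_affines[library]``.  Fully reproducible from
    (params, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(length_spec, int):
        lo = hi = length_spec
    else:
        lo, hi = length_spec
    if lo < 3 or hi < lo:
        raise ValueError(f"invalid length spec {length_spec!r}")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n)
    base_arr = np.array(list("ACGU"))
    seqs = ["".join(rng.choice(base_arr, size=int(L))) for L in lengths]
    clean = [oracle_mrl(s, params) for s in seqs]
    scale, bias = params.library_affines[library]
    noise = rng.normal(0.0, params.noise_sd, size=n)
    mrl = scale * (np.asarray(clean) + noise) + bias
    return MRLDataset.from_arrays(seqs, mrl, np.full(n, library, dtype=np.int64))


def mrl_from_polysome_fractions(counts, ribosomes) -> float:
    """Mean ribosome load from polysome-profiling fractions.

    ``sum_i ribosomes_i * counts_i / sum_i counts_i`` — the
    abundance-weighted mean ribosome number; invariant to rescaling counts.
    """
    counts = np.asarray(counts, dtype=np.float64)
    ribosomes = np.asarray(ribosomes, dtype=np.float64)
    if counts.shape != ribosomes.shape:
        raise ValueError("counts and ribosomes must have the same length")
    if np.any(counts < 0) or np.any(ribosomes < 0):
        raise ValueError("counts and ribosome numbers must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total counts must be > 0")
    return float((ribosomes * counts).sum() / total)
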
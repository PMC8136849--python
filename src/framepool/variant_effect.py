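"""VCF + BED + FASTA variant scoring for 5'UTR variants.

The pipeline loads 5'UTR exon regions (BED, 0-based half-open, one row per
exon, grouped by transcript name), extracts the spliced, strand-aware
reference 5'UTR from an indexed FASTA, injects intersecting VCF variants
(SNVs and indels) into transcript coordinates, and reports per
(transcript, variant) the log2 fold change of predicted MRL, plus the same
score recomputed after simulating a frameshift by appending one or two
masked zero positions at the 3' end of both sequences.  The shifted scores
expose variants that act within the canonical reading frame (e.g. an
in-frame uAUG that merely extends the protein scores ~0 unshifted but
strongly negative once shifted out of frame).

Any predictor with the ``predict_sequences(seqs, library=None,
frame_shift=0)`` surface can be plugged in — a trained model or the
simulator oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_core import NucSequence, as_sequence

__all__ = [
    "TranscriptUTR",
    "Variant",
    "VariantEffect",
    "load_utr_regions",
    "load_variants",
    "extract_utr_sequence",
    "apply_variants",
    "score_variants",
    "run_vcf_pipeline",
]

logger = logging.getLogger("framepool")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp_dna(s: str) -> str:
    return s.upper().translate(_DNA_COMPLEMENT)[::-1]


def _dna_to_rna(s: str) -> str:
    return s.upper().replace("T", "U")


@dataclass(frozen=True)
class TranscriptUTR:
    """Spliced 5'UTR of one transcript: exon intervals in genomic order.

    Intervals are 0-based half-open, non-overlapping and sorted ascending;
    transcript order is 5'->3' (for '-' transcripts that is the reversed
    interval traversal with reverse complement).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple  # of (start, end)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if not 0 <= start < end:
                raise ValueError(
                    f"{self.transcript_id}: malformed interval [{start}, {end})"
                )
            if start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping/unsorted exon intervals"
                )
            prev_end = end

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    def genomic_offset(self, gpos: int, span: int = 1) -> int:
        """Offset of genomic position ``gpos`` (0-based) within the
        ascending exon concatenation; the ``span`` bases starting there must
        lie inside a single exon."""
        off = 0
        for start, end in self.exons:
            if start <= gpos < end:
                if gpos + span > end:
                    raise ValueError(
                        f"{self.transcript_id}: span [{gpos}, {gpos + span}) "
                        f"crosses the exon boundary at {end}"
                    )
                return off + (gpos - start)
            off += end - start
        raise ValueError(
            f"{self.transcript_id}: genomic position {gpos} not in any exon"
        )

    def overlaps(self, gpos: int, span: int = 1) -> bool:
        """True if the span [gpos, gpos+span) touches any exon (a touching
        but boundary-crossing variant is an intersection that later fails
        injection with a diagnostic, not a silent exclusion)."""
        return any(gpos < e and gpos + span > s for s, e in self.exons)


@dataclass(frozen=True)
class Variant:
    """A biallelic variant; ``pos`` is the 1-based position of the first
    REF base, alleles are genomic plus-strand DNA."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError(f"{self.id}: empty allele")


@dataclass(frozen=True)
class VariantEffect:
    transcript_id: str
    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mrl_ref: float
    mrl_alt: float
    log2fc: float
    log2fc_shift1: float
    log2fc_shift2: float
    error: str | None = None


def load_utr_regions(bed_path) -> list[TranscriptUTR]:
    """Read 5'UTR exon regions from a BED6+ file, one transcript per name.

    Chromosome and strand must be consistent within a transcript.
    """
    rows = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{bed_path}:{ln}: BED6+ required (got {len(fields)} columns)")
            chrom, start, end, name, _score, strand = fields[:6]
            rows.append((name, chrom, int(start), int(end), strand))
    out: dict[str, dict] = {}
    for name, chrom, start, end, strand in rows:
        rec = out.setdefault(name, {"chrom": chrom, "strand": strand, "exons": []})
        if rec["chrom"] != chrom or rec["strand"] != strand:
            raise ValueError(f"transcript {name}: inconsistent chrom/strand across rows")
        rec["exons"].append((start, end))
    return [
        TranscriptUTR(
            transcript_id=name,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
        )
        for name, rec in out.items()
    ]


def load_variants(vcf_path) -> list[Variant]:
    """Read variants from a VCF (plain or bgzipped); multi-allelic records
    are split into biallelic ones; symbolic alleles are skipped."""
    import pysam

    out = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if not set(alt.upper()) <= set("ACGTN"):
                    logger.warning("skipping symbolic allele %s at %s:%d", alt, rec.chrom, rec.pos)
                    continue
                vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}>{alt}"
                out.append(
                    Variant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref.upper(),
                            alt=alt.upper(), id=vid)
                )
    return out


def extract_utr_sequence(utr: TranscriptUTR, genome) -> NucSequence:
    """Spliced 5'->3' UTR sequence from a ``pyfaidx.Fasta`` genome, mapped
    to the RNA alphabet (reverse-complemented for '-' transcripts)."""
    if utr.chrom not in genome:
        raise KeyError(f"contig {utr.chrom!r} missing from the FASTA")
    contig_len = len(genome[utr.chrom])
    parts = []
    for start, end in utr.exons:
        if end > contig_len:
            raise ValueError(
                f"{utr.transcript_id}: interval [{start}, {end}) exceeds "
                f"contig {utr.chrom} length {contig_len}"
            )
        parts.append(str(genome[utr.chrom][start:end]).upper())
    dna = "".join(parts)
    if utr.strand == "-":
        dna = _revcomp_dna(dna)
    return NucSequence(_dna_to_rna(dna))


def apply_variants(
    utr: TranscriptUTR, ref_seq: "NucSequence | str", variants
) -> NucSequence:
    """Inject variants into the transcript sequence (strand-aware).

    Every variant must match the reference and lie fully inside one exon;
    overlapping variants are rejected.  Edits are applied right-to-left in
    transcript coordinates so earlier edits do not shift later ones.
    """
    ref_seq = as_sequence(ref_seq)
    L = len(ref_seq)
    edits = []  # (t_start, t_len, replacement RNA string)
    for v in variants:
        if v.chrom != utr.chrom:
            raise ValueError(f"{v.id}: chrom {v.chrom} != transcript chrom {utr.chrom}")
        g0 = v.pos - 1
        rl = len(v.ref)
        off = utr.genomic_offset(g0, span=rl)
        if utr.strand == "+":
            t_start = off
            ref_rna = _dna_to_rna(v.ref)
            alt_rna = _dna_to_rna(v.alt)
        else:
            t_start = L - (off + rl)
            ref_rna = _dna_to_rna(_revcomp_dna(v.ref))
            alt_rna = _dna_to_rna(_revcomp_dna(v.alt))
        found = ref_seq.bases[t_start : t_start + rl]
        if found != ref_rna:
            raise ValueError(
                f"{v.id}: REF mismatch at transcript position {t_start} of "
                f"{utr.transcript_id}: expected {ref_rna}, found {found}"
            )
        edits.append((t_start, rl, alt_rna))
    edits.sort(key=lambda e: e[0])
    for (s1, l1, _), (s2, _, _) in zip(edits, edits[1:]):
        if s1 + l1 > s2:
            raise ValueError(
                f"overlapping variants in {utr.transcript_id} at transcript "
                f"positions {s1} and {s2}"
            )
    bases = ref_seq.bases
    for t_start, t_len, alt_rna in reversed(edits):
        bases = bases[:t_start] + alt_rna + bases[t_start + t_len :]
    return NucSequence(bases)


def _log2fc(alt: float, ref: float) -> float:
    return float(np.log2(alt / ref))


def score_variants(
    predictor,
    ref_seq: "NucSequence | str",
    alt_seq: "NucSequence | str",
    library=None,
    variant_meta: dict | None = None,
) -> VariantEffect:
    """Score one ref/alt pair: unshifted log2 fold change plus the two
    simulated-frameshift scores (both sequences extended by k masked zero
    positions at the 3' end, k = 1, 2)."""
    ref_seq = as_sequence(ref_seq)
    alt_seq = as_sequence(alt_seq)
    meta = variant_meta or {}
    preds = {}
    for k in (0, 1, 2):
        pr, pa = predictor.predict_sequences(
            [ref_seq, alt_seq], library=library, frame_shift=k
        )
        preds[k] = (float(pr), float(pa))
    error = None
    if any(p <= 0 for pair in preds.values() for p in pair):
        error = "non-positive MRL prediction; log2 fold change undefined"
        fcs = {k: float("nan") for k in (0, 1, 2)}
    else:
        fcs = {k: _log2fc(pa, pr) for k, (pr, pa) in preds.items()}
    return VariantEffect(
        transcript_id=meta.get("transcript_id", ""),
        variant_id=meta.get("variant_id", ""),
        chrom=meta.get("chrom", ""),
        pos=meta.get("pos", 0),
        ref=meta.get("ref", ""),
        alt=meta.get("alt", ""),
        mrl_ref=preds[0][0],
        mrl_alt=preds[0][1],
        log2fc=fcs[0],
        log2fc_shift1=fcs[1],
        log2fc_shift2=fcs[2],
        error=error,
    )


def run_vcf_pipeline(
    vcf_path, bed_path, fasta_path, predictor, library=None
) -> pd.DataFrame:
    """Score every (transcript, variant) intersection.

    Returns one row per intersection, ordered by (transcript id, position);
    an empty intersection yields an empty table.  Variants that fail
    injection (REF mismatch, exon-boundary span) become error rows with NaN
    scores rather than aborting the run.
    """
    import pyfaidx

    utrs = load_utr_regions(bed_path)
    variants = load_variants(vcf_path)
    genome = pyfaidx.Fasta(str(fasta_path))
    rows = []
    for utr in sorted(utrs, key=lambda u: u.transcript_id):
        hits = [
            v
            for v in variants
            if v.chrom == utr.chrom and utr.overlaps(v.pos - 1, span=len(v.ref))
        ]
        if not hits:
            continue
        ref_seq = extract_utr_sequence(utr, genome)
        for v in sorted(hits, key=lambda v: (v.pos, v.alt)):
            meta = {
                "transcript_id": utr.transcript_id,
                "variant_id": v.id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
            }
            try:
                alt_seq = apply_variants(utr, ref_seq, [v])
            except ValueError as exc:
                rows.append(
                    VariantEffect(
                        **meta, mrl_ref=float("nan"), mrl_alt=float("nan"),
                        log2fc=float("nan"), log2fc_shift1=float("nan"),
                        log2fc_shift2=float("nan"), error=str(exc),
                    )
                )
                continue
            rows.append(
                score_variants(predictor, ref_seq, alt_seq, library=library,
                               variant_meta=meta)
            )
    cols = [
        "transcript_id", "variant_id", "chrom", "pos", "ref", "alt",
        "mrl_ref", "mrl_alt", "log2fc", "log2fc_shift1", "log2fc_shift2",
        "error",
    ]
    return pd.DataFrame([vars(r) for r in rows], columns=cols)
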
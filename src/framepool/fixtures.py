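"""Synthetic toy fixtures: genome FASTA, 5'UTR BED, VCF and TIS contexts.

Everything here is constructed, hand-checkable data (no real genome): a
50 nt uTIS-free reference 5'UTR over {C, A} with two ``ACG`` seeds placed
so that a single C->U substitution creates either an out-of-frame uAUG
(transcript position 10, frame 1) or an in-frame uAUG (position 20,
frame 0).  The same UTR is embedded on a plus-strand transcript, a
minus-strand transcript (reverse-complemented) and a two-exon spliced
transcript, giving the variant pipeline exactly computable expected scores
under the simulator oracle.  The TIS context table holds the 16
{-3 base} x {+4 base} AUG contexts plus filtered and alternative-codon
examples, with measured strengths taken from the simulator's own
initiation model.
"""

from __future__ import annotations

from pathlib import Path

from .synthetic_mpra import DEFAULT_PARAMS, ScanningParams, _context_score
from .tis_strength import TISContext, has_unintended_aug
from .variant_effect import _revcomp_dna

__all__ = ["REF_UTR_RNA", "ORACLE_TEST_PARAMS", "make_fixtures"]

# 50 nt, alphabet {C, A} + two ACG seeds; no AUG/CUG/GUG, no U at all.
# ACG at 10..12 (frame 1: out-of-frame once the C at 11 becomes U) and
# ACG at 20..22 (frame 0: in-frame).
REF_UTR_RNA = "CCACCACCAC" + "ACG" + "CCACCAC" + "ACG" + "CCACCACCACCACCACCACCACCACCA"
assert len(REF_UTR_RNA) == 50 and "U" not in REF_UTR_RNA

# Scanning parameters with analytically clean numbers: the logistic factor
# saturates to exactly 1.0, so every uAUG initiates with probability 0.9
# regardless of context, and CUG/GUG are inert.  With mu_main=6, mu_oof=2
# a created out-of-frame uAUG gives oracle MRL 0.9*2 + 0.1*6 = 2.4.
ORACLE_TEST_PARAMS = ScanningParams(
    init_slope=0.0,
    init_intercept=500.0,
    codon_strength=(("AUG", 0.9), ("CUG", 0.0), ("GUG", 0.0)),
    noise_sd=0.0,
)


def _fasta_write(path: Path, records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _context_strength(ctx: TISContext, params: ScanningParams) -> float:
    """Initiation probability of the context under the scanning model
    (codon at offset 6 of the assembled window, full window present)."""
    window = ctx.assemble(True)
    pos = len(ctx.upstream)
    score = _context_score(window, pos, params.kozak_pwm)
    return params.init_probability(score, ctx.codon)


def make_fixtures(outdir, params: ScanningParams = DEFAULT_PARAMS) -> dict[str, Path]:
    """Write the toy genome, BED, VCF and context CSV into ``outdir``.

    Returns a dict of the created paths (keys: fasta, bed, vcf, contexts).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    utr_dna = REF_UTR_RNA.replace("U", "T")

    # chr1: plus-strand single-exon UTR at [10, 60)
    chr1 = "G" * 10 + utr_dna + "G" * 10
    # chr2: minus-strand single-exon UTR at [10, 60)
    chr2 = "G" * 10 + _revcomp_dna(utr_dna) + "G" * 10
    # chr3: plus-strand UTR spliced over [5, 30) + [40, 65)
    chr3 = "G" * 5 + utr_dna[:25] + "G" * 10 + utr_dna[25:] + "G" * 5
    fasta = outdir / "toy_genome.fa"
    _fasta_write(fasta, {"chr1": chr1, "chr2": chr2, "chr3": chr3})
    for suffix in (".fai",):  # force re-indexing of a fresh file
        idx = Path(str(fasta) + suffix)
        if idx.exists():
            idx.unlink()

    bed = outdir / "toy_utrs.bed"
    bed.write_text(
        "\n".join(
            [
                "chr1\t10\t60\ttx_plus\t0\t+",
                "chr2\t10\t60\ttx_minus\t0\t-",
                "chr3\t5\t30\ttx_split\t0\t+",
                "chr3\t40\t65\ttx_split\t0\t+",
            ]
        )
        + "\n"
    )

    # Variants (1-based VCF positions):
    #  - chr1:22 C>T,A  multi-allelic; C>T creates the out-of-frame uAUG at
    #    transcript position 10, C>A is a neutral substitution
    #  - chr1:32 C>T    creates the in-frame uAUG at transcript position 20
    #  - chr1:41 C>CA   1 bp insertion (frameshifts all 5'-ward positions)
    #  - chr1:5  G>A    outside every UTR exon: excluded by intersection
    #  - chr2:49 G>A    minus strand: same out-of-frame uAUG as chr1:22 C>T
    #  - chr3:17 C>T    spliced transcript, same out-of-frame uAUG in exon 1
    vcf = outdir / "toy_variants.vcf"
    vcf.write_text(
        "\n".join(
            [
                "##fileformat=VCFv4.2",
                f"##contig=<ID=chr1,length={len(chr1)}>",
                f"##contig=<ID=chr2,length={len(chr2)}>",
                f"##contig=<ID=chr3,length={len(chr3)}>",
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
                "chr1\t22\tvar_oof_uaug\tC\tT,A\t.\tPASS\t.",
                "chr1\t32\tvar_if_uaug\tC\tT\t.\tPASS\t.",
                "chr1\t41\tvar_ins\tC\tCA\t.\tPASS\t.",
                "chr1\t5\tvar_outside\tG\tA\t.\tPASS\t.",
                "chr2\t49\tvar_minus_oof\tG\tA\t.\tPASS\t.",
                "chr3\t17\tvar_split_oof\tC\tT\t.\tPASS\t.",
            ]
        )
        + "\n"
    )

    contexts = outdir / "toy_contexts.csv"
    lines = ["codon,upstream,downstream,strength"]
    for x in "ACGU":
        for y in "ACGU":
            ctx = TISContext(codon="AUG", upstream=f"CCC{x}CC", downstream=f"{y}C")
            strength = _context_strength(ctx, params)
            lines.append(f"AUG,CCC{x}CC,{y}C,{strength:.6f}")
    # a context with an unintended flank AUG (excluded downstream)
    lines.append("AUG,AAUGGG,GG,")
    # alternative start codons (-3..+4 window)
    for codon in ("CUG", "GUG"):
        ctx = TISContext(codon=codon, upstream="ACC", downstream="C")
        assert not has_unintended_aug(ctx)
        lines.append(f"{codon},ACC,C,{_context_strength(ctx, params):.6f}")
    contexts.write_text("\n".join(lines) + "\n")

    return {"fasta": fasta, "bed": bed, "vcf": vcf, "contexts": contexts}
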
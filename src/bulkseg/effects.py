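"""Coding-effect classification of SNVs and indels against gene models.

Each variant is placed against the longest transcript of each gene: coding
SNVs are classified by translating the reference and alternate codons with
the standard genetic code (strand-aware), coding indels by whether their
length change preserves the reading frame, and non-coding variants as
splice-adjacent (within 2 bp of a CDS boundary on the intron side),
intronic, or intergenic.  "Impact" variants are those in
{nonsynonymous, stop_gain, stop_loss, frameshift}.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
from Bio.Seq import Seq

IMPACT_EFFECTS = {"nonsynonymous", "stop_gain", "stop_loss", "frameshift"}

#: severity precedence for variants overlapping several categories
SEVERITY = ["frameshift", "stop_gain", "stop_loss", "nonsynonymous", "inframe_indel",
            "splice_adjacent", "synonymous", "intronic", "intergenic"]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str                       # '+' or '-'
    cds: list[tuple[int, int]]        # 1-based inclusive, ascending genomic order
    start: int = 0                    # gene feature bounds (default: CDS bounds)
    end: int = 0

    def __post_init__(self) -> None:
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
        if not self.start:
            self.start = self.cds[0][0]
        if not self.end:
            self.end = self.cds[-1][1]
        self.partial = self.cds_length % 3 != 0

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_offset(self, pos: int) -> int | None:
        """0-based position within the spliced CDS in translation order."""
        segments = self.cds if self.strand == "+" else self.cds[::-1]
        cum = 0
        for s, e in segments:
            if s <= pos <= e:
                return cum + (pos - s if self.strand == "+" else e - pos)
            cum += e - s + 1
        return None

    def genomic_pos(self, offset: int) -> int:
        """Inverse of cds_offset."""
        segments = self.cds if self.strand == "+" else self.cds[::-1]
        cum = 0
        for s, e in segments:
            length = e - s + 1
            if offset < cum + length:
                k = offset - cum
                return s + k if self.strand == "+" else e - k
            cum += length
        raise IndexError(f"CDS offset {offset} beyond {self.gene_id}")

    def splice_adjacent(self, pos: int, margin: int = 2) -> bool:
        """Is pos in an intron within ``margin`` bp of a CDS boundary?"""
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if e1 < pos < s2 and (pos - e1 <= margin or s2 - pos <= margin):
                return True
        return False


@dataclass
class EffectCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    effect: str
    codon_change: str | None = None
    aa_change: str | None = None


# ---------------------------------------------------------------------------
# genome / annotation access
# ---------------------------------------------------------------------------

def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice; genome is a pyfaidx.Fasta or a {chrom: str} dict."""
    seq = genome[chrom][start - 1:end]
    return str(getattr(seq, "seq", seq)).upper()


def open_genome(path: str | Path):
    from pyfaidx import Fasta
    return Fasta(str(path))


def load_gene_models(gff_path: str | Path) -> list[GeneModel]:
    """Gene models from GFF3, keeping the longest-CDS transcript per gene."""
    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        best_cds: list[tuple[int, int]] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = [(c.start, c.end) for c in db.children(mrna, featuretype="CDS")]
            if sum(e - s + 1 for s, e in cds) > sum(e - s + 1 for s, e in best_cds):
                best_cds = cds
        if not best_cds:  # CDS directly under gene
            best_cds = [(c.start, c.end) for c in db.children(gene, featuretype="CDS")]
        if not best_cds:
            continue
        models.append(GeneModel(gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                                cds=best_cds, start=gene.start, end=gene.end))
    return models


def translate_cds(model: GeneModel, genome) -> str:
    """Protein sequence of the spliced CDS (stop rendered as '*')."""
    parts = [_fetch(genome, model.chrom, s, e) for s, e in model.cds]
    seq = "".join(parts)
    if model.strand == "-":
        seq = seq[::-1].translate(_COMP)
    return str(Seq(seq).translate())


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _containing_gene(chrom: str, pos: int, models: list[GeneModel]) -> GeneModel | None:
    for m in models:
        if m.chrom == chrom and m.start <= pos <= m.end:
            return m
    return None


def classify_snv(
    chrom: str, pos: int, ref: str, alt: str,
    models: list[GeneModel], genome,
) -> EffectCall:
    """Effect of a single-nucleotide variant (see module docstring)."""
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("classify_snv expects a SNV; use classify_indel")
    genome_base = _fetch(genome, chrom, pos, pos)
    if genome_base != ref.upper():
        raise ValueError(f"reference mismatch at {chrom}:{pos}: "
                         f"variant says {ref}, genome says {genome_base}")
    gene = _containing_gene(chrom, pos, models)
    if gene is None:
        return EffectCall(chrom, pos, ref, alt, None, "intergenic")
    offset = gene.cds_offset(pos)
    if offset is None:
        effect = "splice_adjacent" if gene.splice_adjacent(pos) else "intronic"
        return EffectCall(chrom, pos, ref, alt, gene.gene_id, effect)

    codon_start = offset - offset % 3
    codon_pos = [gene.genomic_pos(codon_start + k) for k in range(3)]
    bases = [_fetch(genome, chrom, p, p) for p in codon_pos]
    if gene.strand == "-":
        bases = [b.translate(_COMP) for b in bases]
    ref_codon = "".join(bases)
    alt_base = alt.upper() if gene.strand == "+" else alt.upper().translate(_COMP)
    k = codon_pos.index(pos)
    alt_codon = ref_codon[:k] + alt_base + ref_codon[k + 1:]

    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "stop_gain"
    elif aa_ref == "*":
        effect = "stop_loss"
    else:
        effect = "nonsynonymous"
    aa_num = offset // 3 + 1
    return EffectCall(chrom, pos, ref, alt, gene.gene_id, effect,
                      codon_change=f"{ref_codon}>{alt_codon}",
                      aa_change=f"{aa_ref}{aa_num}{aa_alt}")


def classify_indel(
    chrom: str, pos: int, ref: str, alt: str, models: list[GeneModel]
) -> EffectCall:
    """Frameshift / in-frame call for an indel by CDS overlap."""
    if len(ref) == 1 and len(alt) == 1:
        raise ValueError("classify_indel expects an indel; use classify_snv")
    span_end = pos + len(ref) - 1
    gene = _containing_gene(chrom, pos, models) or _containing_gene(chrom, span_end, models)
    if gene is None:
        return EffectCall(chrom, pos, ref, alt, None, "intergenic")
    overlaps_cds = any(s <= span_end and pos <= e for s, e in gene.cds)
    if overlaps_cds:
        shift = (len(alt) - len(ref)) % 3
        effect = "frameshift" if shift else "inframe_indel"
    elif gene.splice_adjacent(pos) or gene.splice_adjacent(span_end):
        effect = "splice_adjacent"
    else:
        effect = "intronic"
    return EffectCall(chrom, pos, ref, alt, gene.gene_id, effect)


def classify_variant(chrom, pos, ref, alt, models, genome) -> EffectCall:
    if len(ref) == 1 and len(alt) == 1:
        return classify_snv(chrom, pos, ref, alt, models, genome)
    return classify_indel(chrom, pos, ref, alt, models)


def annotate_variants(df: pd.DataFrame, models: list[GeneModel], genome) -> pd.DataFrame:
    """Effect table for a variant DataFrame (chrom/pos/ref/alt columns)."""
    calls = [classify_variant(r.chrom, int(r.pos), r.ref, r.alt, models, genome)
             for r in df.itertuples(index=False)]
    return pd.DataFrame([c.__dict__ for c in calls])


def summarize_region_effects(
    calls: list[EffectCall] | pd.DataFrame, region=None
) -> dict:
    """Effect counts plus impact and affected-gene totals, optionally region-restricted."""
    if isinstance(calls, pd.DataFrame):
        calls = [EffectCall(**{k: r.get(k) for k in
                               ("chrom", "pos", "ref", "alt", "gene_id", "effect",
                                "codon_change", "aa_change")})
                 for r in calls.to_dict("records")]
    if region is not None:
        calls = [c for c in calls if region.contains(c.chrom, c.pos)]
    counts = Counter(c.effect for c in calls)
    impact = [c for c in calls if c.effect in IMPACT_EFFECTS]
    genes = {c.gene_id for c in impact if c.gene_id is not None}
    return {"effect_counts": dict(counts),
            "n_impact": len(impact),
            "n_affected_genes": len(genes)}
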
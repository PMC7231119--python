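"""Synthetic F2 bulk-sequencing experiments with known ground truth.

Emulates the classic bulked-segregant design: two fully homozygous inbred
parents that differ at SNP/indel markers along each chromosome, an F2
population segregating 1:2:1 at every marker, a single recessive causal
locus, and two bulks of phenotypic extremes sequenced to ~30x with Poisson
depth, binomial allele sampling and a small base-error rate.

Conventions
-----------
The reference genome is taken to be the male-parent side (as when an F2 from
a cross onto the reference species is mapped back to that species' assembly).
Hence the *alt* allele of every emitted variant is the female-parent allele,
and the SNP-index of a bulk counts female-parent reads.  Genotypes are stored
as the dosage of the female-parent allele per marker: 2 = homozygous female
(PP), 1 = heterozygous (PH), 0 = homozygous male (HH).  The recessive
phenotype ("easy dehulling" in the motivating cross) appears iff dosage at
the causal marker is 2.
"""

from __future__ import annotations

import dataclasses
import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SAMPLES = ("KF", "KM", "K21", "K5")  # female parent, male parent, low bulk, high bulk
BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of one simulated bulk-segregant experiment.

    Defaults follow the study design this package models: 150 bp paired
    reads, ~32x mean depth, bulks of 30 extremes drawn from an F2 of 300.
    """

    n_chromosomes: int = 1
    chrom_length_bp: int = 20_000_000
    marker_density: float = 50.0          # markers per Mb
    causal_chrom: str = "chr1"
    causal_pos: int = 6_400_000
    bulk_size: int = 30
    population_size: int = 300
    mean_depth: float = 32.0
    base_error_rate: float = 0.001
    recomb_rate_cM_per_Mb: float = 4.0
    read_length: int = 150
    indel_fraction: float = 0.25          # fraction of markers emitted as indels
    annot_fail_fraction: float = 0.05     # sites given a deliberately failing annotation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")
        if not 0.0 <= self.base_error_rate < 0.5:
            raise ValueError("base_error_rate must be in [0, 0.5)")
        if self.causal_chrom not in self.chrom_names():
            raise ValueError(f"causal_chrom {self.causal_chrom!r} not among chromosomes")
        if not 1 <= self.causal_pos <= self.chrom_length_bp:
            raise ValueError("causal_pos outside the causal chromosome")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class Parents:
    """Marker table shared by both homozygous parents.

    ``markers`` has columns chrom, pos, ref, alt, vtype, is_causal; the female
    parent carries alt/alt at every marker, the male parent ref/ref.
    """

    markers: pd.DataFrame

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def causal_index(self) -> int:
        idx = np.flatnonzero(self.markers["is_causal"].to_numpy())
        return int(idx[0])


@dataclass
class F2Individual:
    """One F2 plant: female-allele dosage per marker and its phenotype."""

    dosage: np.ndarray                 # int8, one of {0,1,2} per marker
    phenotype: str                     # "easy-dehull" | "hard-dehull"


@dataclass
class SimResult:
    config: SimConfig
    parents: Parents
    population: list[F2Individual]
    bulk_low: list[F2Individual]
    bulk_high: list[F2Individual]
    variants: pd.DataFrame             # four-sample variant table (see sequence_experiment)


# ---------------------------------------------------------------------------
# parents and markers
# ---------------------------------------------------------------------------

def simulate_parents(config: SimConfig, rng: np.random.Generator | None = None) -> Parents:
    """Draw divergent homozygous marker sets for the two parents.

    Marker positions are uniform per chromosome at ``marker_density`` per Mb;
    a SNP marker is always placed exactly at the causal position.  Raises if
    the causal chromosome would receive no markers.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    frames = []
    for chrom in config.chrom_names():
        n = rng.poisson(config.marker_density * config.chrom_length_bp / 1e6)
        if chrom == config.causal_chrom and n == 0:
            raise ValueError("marker_density too low: causal chromosome received 0 markers")
        pos = np.sort(rng.choice(config.chrom_length_bp, size=n, replace=False)) + 1
        if chrom == config.causal_chrom:
            pos = np.unique(np.append(pos, config.causal_pos))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos.astype(np.int64)}))
    markers = pd.concat(frames, ignore_index=True)

    m = len(markers)
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    ref = BASES[ref_idx].astype(object)
    alt = BASES[alt_idx].astype(object)

    is_causal = (
        (markers["chrom"] == config.causal_chrom) & (markers["pos"] == config.causal_pos)
    ).to_numpy()
    is_indel = (rng.random(m) < config.indel_fraction) & ~is_causal
    ins_len = rng.integers(1, 4, size=m)
    for i in np.flatnonzero(is_indel):
        extra = "".join(rng.choice(BASES, size=ins_len[i]))
        if rng.random() < 0.5:
            alt[i] = ref[i] + extra          # insertion
        else:
            ref[i], alt[i] = ref[i] + extra, ref[i]  # deletion

    markers["ref"] = ref
    markers["alt"] = alt
    markers["vtype"] = np.where(is_indel, "indel", "SNP")
    markers["is_causal"] = is_causal
    return Parents(markers=markers)


# ---------------------------------------------------------------------------
# F2 population
# ---------------------------------------------------------------------------

def _chrom_blocks(parents: Parents) -> list[tuple[np.ndarray, np.ndarray]]:
    """(row indices, positions) per chromosome, extracted once per population."""
    return [
        (sub.index.to_numpy(), sub["pos"].to_numpy())
        for _, sub in parents.markers.groupby("chrom", sort=False)
    ]


def _gamete_into(
    out: np.ndarray, blocks, morgans: float, chrom_length: int, rng: np.random.Generator
) -> None:
    for idx, pos in blocks:
        phase = rng.integers(0, 2)
        n_xo = rng.poisson(morgans)
        xo = np.sort(rng.uniform(0, chrom_length, size=n_xo))
        out[idx] = (phase + np.searchsorted(xo, pos)) % 2


def _gamete(parents: Parents, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete: 1 = female-parent allele, per marker.

    Crossovers per chromosome are Poisson with mean equal to the map length
    in Morgans (Haldane model, no interference), placed uniformly.
    """
    out = np.empty(parents.n_markers, dtype=np.int8)
    morgans = config.chrom_length_bp / 1e6 * config.recomb_rate_cM_per_Mb / 100.0
    _gamete_into(out, _chrom_blocks(parents), morgans, config.chrom_length_bp, rng)
    return out


def simulate_f2_population(
    parents: Parents, n_individuals: int, config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[F2Individual]:
    """Self the F1 to produce ``n_individuals`` F2 plants.

    Each plant is the sum of two independent recombinant gametes, so single-
    marker genotypes segregate 1:2:1 and the recessive phenotype appears in
    ~1/4 of plants.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ci = parents.causal_index()
    blocks = _chrom_blocks(parents)
    morgans = config.chrom_length_bp / 1e6 * config.recomb_rate_cM_per_Mb / 100.0
    g1 = np.empty(parents.n_markers, dtype=np.int8)
    g2 = np.empty(parents.n_markers, dtype=np.int8)
    pop = []
    for _ in range(n_individuals):
        _gamete_into(g1, blocks, morgans, config.chrom_length_bp, rng)
        _gamete_into(g2, blocks, morgans, config.chrom_length_bp, rng)
        dosage = (g1 + g2).astype(np.int8)
        phen = "easy-dehull" if dosage[ci] == 2 else "hard-dehull"
        pop.append(F2Individual(dosage=dosage, phenotype=phen))
    return pop


def build_bulks(
    population: list[F2Individual], bulk_size: int
) -> tuple[list[F2Individual], list[F2Individual]]:
    """Pool ``bulk_size`` plants from each phenotypic extreme.

    The low bulk is all recessive-phenotype plants (homozygous female at the
    causal locus); the high bulk segregates PH:HH = 2:1 in expectation.
    """
    easy = [ind for ind in population if ind.phenotype == "easy-dehull"]
    hard = [ind for ind in population if ind.phenotype == "hard-dehull"]
    for name, group in (("easy-dehull", easy), ("hard-dehull", hard)):
        if len(group) < bulk_size:
            raise ValueError(
                f"insufficient {name} individuals: need {bulk_size}, have {len(group)}"
            )
    return easy[:bulk_size], hard[:bulk_size]


# ---------------------------------------------------------------------------
# sequencing
# ---------------------------------------------------------------------------

def _bulk_alt_freq(bulk: list[F2Individual]) -> np.ndarray:
    dosage = np.stack([ind.dosage for ind in bulk])
    return dosage.sum(axis=0) / (2 * len(bulk))


def sequence_bulk(
    bulk: list[F2Individual], parents: Parents, config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker (ref_depth, alt_depth) for a pooled DNA sample.

    Total depth is Poisson(mean_depth); each read samples a uniformly random
    chromosome copy in the pool and reports its allele, miscalled with
    probability ``base_error_rate`` — equivalently alt reads are
    Binomial(depth, p(1-e) + (1-p)e) for pool alt frequency p.
    """
    if not bulk:
        raise ValueError("bulk must be nonempty")
    p = _bulk_alt_freq(bulk)
    e = config.base_error_rate
    p_read = p * (1 - e) + (1 - p) * e
    depth = rng.poisson(config.mean_depth, size=parents.n_markers)
    alt = rng.binomial(depth, p_read)
    return depth - alt, alt


def _haploid_freqs(parents: Parents) -> dict[str, np.ndarray]:
    m = parents.n_markers
    return {"KF": np.ones(m), "KM": np.zeros(m)}


def _call_gt(ref_d: np.ndarray, alt_d: np.ndarray) -> np.ndarray:
    """Naive genotype call from allele depths (./., 0/0, 0/1 or 1/1)."""
    total = ref_d + alt_d
    frac = np.divide(alt_d, total, out=np.full(len(total), np.nan), where=total > 0)
    gt = np.full(len(total), "./.", dtype=object)
    gt[frac <= 0.1] = "0/0"
    gt[(frac > 0.1) & (frac < 0.9)] = "0/1"
    gt[frac >= 0.9] = "1/1"
    return gt


def sequence_experiment(
    parents: Parents,
    bulk_low: list[F2Individual],
    bulk_high: list[F2Individual],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Four-sample variant table (parents KF/KM, bulks K21/K5).

    Site annotations FS/MQ/QD and per-sample GQ are drawn from "pass"
    distributions, except for a configured fraction of sites that get one
    deliberately failing annotation so the hard-filter stage has work to do.
    Parent genotypes are their true homozygous states; bulk genotypes are
    naive depth-ratio calls.
    """
    mk = parents.markers
    m = len(mk)
    df = mk[["chrom", "pos", "ref", "alt", "vtype", "is_causal"]].copy()

    # site annotations: mostly passing draws
    fs = rng.exponential(7.0, size=m)
    mq = rng.normal(60.0, 1.5, size=m)
    qd = np.clip(rng.normal(20.0, 6.0, size=m), 4.5, None)
    gq = {s: rng.integers(30, 100, size=m).astype(float) for s in SAMPLES}

    # deliberate failures: one failing annotation per chosen site
    fail = rng.random(m) < config.annot_fail_fraction
    which = rng.integers(0, 4, size=m)
    fs[fail & (which == 0)] = rng.uniform(60, 250, size=int((fail & (which == 0)).sum()))
    mq[fail & (which == 1)] = rng.uniform(10, 40, size=int((fail & (which == 1)).sum()))
    qd[fail & (which == 2)] = rng.uniform(0, 4, size=int((fail & (which == 2)).sum()))
    for s in ("K21", "K5"):
        sel = fail & (which == 3)
        gq[s][sel] = rng.integers(0, 21, size=int(sel.sum())).astype(float)
    df["fs"], df["mq"], df["qd"] = fs, mq, qd

    pools = {
        "KF": None, "KM": None,  # haploid-equivalent parents handled below
        "K21": bulk_low, "K5": bulk_high,
    }
    e = config.base_error_rate
    for sample in SAMPLES:
        if pools[sample] is None:
            p_read = _haploid_freqs(parents)[sample] * (1 - 2 * e) + e
            depth = rng.poisson(config.mean_depth, size=m)
            alt_d = rng.binomial(depth, p_read)
            ref_d = depth - alt_d
            gt = np.full(m, "1/1" if sample == "KF" else "0/0", dtype=object)
        else:
            ref_d, alt_d = sequence_bulk(pools[sample], parents, config, rng)
            gt = _call_gt(ref_d, alt_d)
        df[f"{sample}_gt"] = gt
        df[f"{sample}_gq"] = gq[sample]
        df[f"{sample}_ad_ref"] = ref_d
        df[f"{sample}_ad_alt"] = alt_d
    return df


def simulate_experiment(config: SimConfig) -> SimResult:
    """Run the full generator: parents -> F2 -> bulks -> variant table."""
    rng = np.random.default_rng(config.seed)
    parents = simulate_parents(config, rng)
    population = simulate_f2_population(parents, config.population_size, config, rng)
    bulk_low, bulk_high = build_bulks(population, config.bulk_size)
    variants = sequence_experiment(parents, bulk_low, bulk_high, config, rng)
    return SimResult(config, parents, population, bulk_low, bulk_high, variants)


# ---------------------------------------------------------------------------
# FASTQ emission (exercises the read trimmer; no alignment realism intended)
# ---------------------------------------------------------------------------

def emit_fastq(
    n_pairs: int,
    config: SimConfig,
    out1: str | Path,
    out2: str | Path,
    rng: np.random.Generator | None = None,
    low_qual_tail_rate: float = 0.0,
    tail_quality: int = 2,
) -> None:
    """Write paired 4-line FASTQ (Phred+33, gzip if the name ends .gz).

    Bases are random; qualities are Q40 throughout except that a fraction
    ``low_qual_tail_rate`` of reads get a low-quality 3' tail of quality
    ``tail_quality`` starting at a uniform position, to give the sliding-
    window trimmer something to cut.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.read_length

    def records(mate: int):
        rng_local_pairs = n_pairs
        for i in range(rng_local_pairs):
            seq = "".join(rng.choice(BASES, size=L))
            qual = np.full(L, 40, dtype=int)
            if rng.random() < low_qual_tail_rate:
                start = int(rng.integers(10, L))
                qual[start:] = tail_quality
            qstr = "".join(chr(q + 33) for q in qual)
            yield f"@sim_pair_{i}/{mate}\n{seq}\n+\n{qstr}\n"

    for path, mate in ((out1, 1), (out2, 2)):
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for rec in records(mate):
                fh.write(rec)


# ---------------------------------------------------------------------------
# small annotated genome for the effect annotator
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGT", "TGCA")


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random internal non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(0, 3)])
    return "".join(codons)


def simulate_annotated_genome(
    rng: np.random.Generator,
    chrom: str = "chrA",
    n_genes: int = 6,
    n_codons: int = 60,
    intron_len: int = 90,
    spacer_len: int = 400,
) -> tuple[str, list[dict]]:
    """A toy genome sequence plus gene models with multi-exon CDS.

    Genes alternate strand; each CDS is split into two exons by one intron.
    Returns (sequence, gene dicts with keys gene_id/chrom/strand/cds), where
    cds is a list of 1-based inclusive (start, end) genomic intervals.
    Every CDS translates with no internal stop codon by construction.
    """
    seq_parts: list[str] = []
    genes: list[dict] = []
    cursor = 0
    for g in range(n_genes):
        spacer = "".join(rng.choice(BASES, size=spacer_len))
        seq_parts.append(spacer)
        cursor += spacer_len
        cds_seq = _random_cds(n_codons, rng)
        strand = "+" if g % 2 == 0 else "-"
        if strand == "-":
            cds_seq = cds_seq[::-1].translate(_COMP)
        cut = 3 * (n_codons // 2)  # split on a codon boundary in genomic coords
        exon1, exon2 = cds_seq[:cut], cds_seq[cut:]
        intron = "".join(rng.choice(BASES, size=intron_len))
        start1 = cursor + 1
        end1 = cursor + len(exon1)
        start2 = end1 + intron_len + 1
        end2 = start2 + len(exon2) - 1
        seq_parts.extend([exon1, intron, exon2])
        cursor = end2
        genes.append({
            "gene_id": f"gene{g + 1}",
            "chrom": chrom,
            "strand": strand,
            "cds": [(start1, end1), (start2, end2)],
        })
    seq_parts.append("".join(rng.choice(BASES, size=spacer_len)))
    return "".join(seq_parts), genes


def write_annotated_genome(
    sequence: str, genes: list[dict], fasta_path: str | Path, gff_path: str | Path,
    chrom: str = "chrA",
) -> None:
    """Write the toy genome as FASTA + GFF3 (gene/mRNA/CDS with phase)."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i:i + 70] + "\n")
    lines = ["##gff-version 3"]
    for g in genes:
        segs = g["cds"]
        gstart, gend = segs[0][0], segs[-1][1]
        gid, strand = g["gene_id"], g["strand"]
        lines.append(f"{chrom}\tsim\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid}")
        lines.append(
            f"{chrom}\tsim\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid}.t1;Parent={gid}"
        )
        order = segs if strand == "+" else segs[::-1]
        cum = 0
        for start, end in order:
            phase = (3 - cum % 3) % 3
            lines.append(
                f"{chrom}\tsim\tCDS\t{start}\t{end}\t.\t{strand}\t{phase}\t"
                f"ID={gid}.t1.cds;Parent={gid}.t1"
            )
            cum += end - start + 1
    Path(gff_path).write_text("\n".join(lines) + "\n")


def write_truth_bed(config: SimConfig, path: str | Path) -> None:
    """Ground-truth causal locus as BED (0-based half-open)."""
    Path(path).write_text(
        f"{config.causal_chrom}\t{config.causal_pos - 1}\t{config.causal_pos}\tcausal_locus\n"
    )
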
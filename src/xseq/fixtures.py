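"""Deterministic synthetic genome / gene-model / read-set generator.

Produces a toy genome (FASTA), a gene annotation (GTF) and aligned reads
(text SAM) whose correct per-gene counts are known by construction, so the
whole counting pipeline can be tested end to end without downloads.

Genes are laid out with fixed exon/intron structures; a configurable
fraction is placed overlapping its neighbour (same strand) to create
designed ambiguity. Fragments are sampled from spliced transcript
coordinates and written with correct M/N CIGARs, flags and mate fields;
designated fractions become multi-mapped (NH tag plus a duplicated
secondary alignment), unaligned, or intergenic no-feature probes.

The recorded :class:`FixtureTruth` is computed by a brute-force per-base
geometric oracle over the generator's own gene layout — deliberately
independent of the step-array containers, the SAM/CIGAR parsing and the
counting code it is used to validate.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from functools import reduce
from pathlib import Path

from .core import flip_strand, reverse_complement

_TAIL_ZONE = 2000  # gene-free region at each chromosome end
_GENE_GAP = 400
_LEFT_MARGIN = 100

MODES = ("union", "intersection-strict", "intersection-nonempty")
STRANDED = ("yes", "no", "reverse")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a desk-scale two-chromosome genome with 50
    three-exon genes, a fifth of them overlapping a neighbour, and 20 000
    paired 75 bp fragments of which 5% each are multi-mapped, unaligned,
    or intergenic probes.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 100_000
    n_genes: int = 50
    exons_per_gene: int = 3
    exon_len: int = 300
    intron_len: int = 200
    overlap_fraction: float = 0.2
    n_fragments: int = 20_000
    read_len: int = 75
    paired: bool = True
    error_rate: float = 0.005
    multimap_fraction: float = 0.05
    unaligned_fraction: float = 0.05
    nofeature_fraction: float = 0.05

    def __post_init__(self):
        for name in (
            "n_chroms",
            "chrom_len",
            "n_genes",
            "exons_per_gene",
            "exon_len",
            "intron_len",
            "n_fragments",
            "read_len",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "overlap_fraction",
            "error_rate",
            "multimap_fraction",
            "unaligned_fraction",
            "nofeature_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.exons_per_gene * self.exon_len < 2 * self.read_len:
            raise ValueError(
                "transcripts shorter than a fragment: increase exon count "
                "or length, or shorten reads"
            )


@dataclass(frozen=True)
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def transcript_len(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class FixtureTruth:
    """Expected counting outcomes, per mode x strandedness.

    ``counts["<mode>|<stranded>"]`` maps gene ids (all of them, including
    zero-count genes) and "__"-prefixed special categories to expected
    unit counts; each table sums to ``n_units`` by construction.
    """

    gene_ids: list[str]
    n_units: int
    counts: dict[str, dict[str, int]]

    def table(self, mode: str, stranded: str) -> dict[str, int]:
        return dict(self.counts[f"{mode}|{stranded}"])

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@dataclass
class FixtureResult:
    spec: FixtureSpec
    fasta: str
    gtf: str
    sam: str
    truth: FixtureTruth
    genes: list[_Gene] = field(default_factory=list)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, text in [
            ("genome.fa", self.fasta),
            ("genes.gtf", self.gtf),
            ("reads.sam", self.sam),
            ("truth.json", self.truth.to_json()),
        ]:
            p = outdir / name
            p.write_text(text)
            paths[name] = p
        return paths


# ---------------------------------------------------------------------------
# layout


def _place_genes(spec: FixtureSpec, rng: random.Random) -> list[_Gene]:
    span = (
        spec.exons_per_gene * spec.exon_len
        + (spec.exons_per_gene - 1) * spec.intron_len
    )
    limit = spec.chrom_len - _TAIL_ZONE
    genes: list[_Gene] = []
    ci = 0
    cursor = _LEFT_MARGIN
    prev: _Gene | None = None
    for g in range(spec.n_genes):
        placed = False
        while not placed:
            if ci >= spec.n_chroms:
                raise ValueError(
                    f"cannot fit {spec.n_genes} genes of span {span} into "
                    f"{spec.n_chroms} chromosome(s) of length {spec.chrom_len}"
                )
            overlap = (
                prev is not None
                and spec.exons_per_gene > 0
                and rng.random() < spec.overlap_fraction
            )
            if overlap:
                start = prev.exons[-1][0] + spec.exon_len // 2
                strand = prev.strand
            else:
                start = cursor
                strand = rng.choice("+-")
            end = start + span
            if end > limit:
                ci += 1
                cursor = _LEFT_MARGIN
                prev = None
                continue
            exons = tuple(
                (
                    start + k * (spec.exon_len + spec.intron_len),
                    start + k * (spec.exon_len + spec.intron_len) + spec.exon_len,
                )
                for k in range(spec.exons_per_gene)
            )
            gene = _Gene(f"G{g + 1:04d}", f"chr{ci + 1}", strand, exons)
            genes.append(gene)
            cursor = max(cursor, end + _GENE_GAP)
            prev = gene
            placed = True
    return genes


def _transcript_to_blocks(
    gene: _Gene, t0: int, t1: int
) -> list[tuple[int, int]]:
    """Genomic blocks (ascending) for transcript range [t0, t1).

    Transcript coordinates run 5'->3' along the gene; for minus-strand
    genes that is right to left on the genome, handled by mirroring into
    the plus-direction walk.
    """
    if gene.strand == "-":
        L = gene.transcript_len
        t0, t1 = L - t1, L - t0
    blocks: list[tuple[int, int]] = []
    offset = 0
    for s, e in gene.exons:
        elen = e - s
        lo, hi = max(t0, offset), min(t1, offset + elen)
        if lo < hi:
            blocks.append((s + lo - offset, s + hi - offset))
        offset += elen
    return blocks


# ---------------------------------------------------------------------------
# truth oracle (brute-force geometry, independent of the library containers)


class _TruthOracle:
    def __init__(self, genes: list[_Gene]):
        self.exons_by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
        for gene in genes:
            lst = self.exons_by_chrom.setdefault(gene.chrom, [])
            for s, e in gene.exons:
                lst.append((s, e, gene.strand, gene.gene_id))

    def segment_sets(
        self, chrom: str, s: int, e: int, strand_filter: str | None
    ) -> list[frozenset]:
        """Distinct per-base gene sets over [s, e), as a run partition."""
        exs = [
            x
            for x in self.exons_by_chrom.get(chrom, [])
            if x[0] < e and s < x[1]
            and (strand_filter is None or x[2] == strand_filter)
        ]
        cuts = sorted(
            {s, e}
            | {max(s, x[0]) for x in exs}
            | {min(e, x[1]) for x in exs}
        )
        return [
            frozenset(x[3] for x in exs if x[0] <= a < x[1])
            for a, b in zip(cuts, cuts[1:])
        ]

    def assign(
        self,
        mates: list[tuple[str, list[tuple[int, int]], str, str]],
        mode: str,
        stranded: str,
    ) -> str:
        """mates: list of (chrom, blocks, read_strand, role)."""
        sets: list[frozenset] = []
        for chrom, blocks, read_strand, role in mates:
            if stranded == "no":
                eff = None
            else:
                first = role in ("first", "single")
                if stranded == "yes":
                    eff = read_strand if first else flip_strand(read_strand)
                else:
                    eff = flip_strand(read_strand) if first else read_strand
            for s, e in blocks:
                sets.extend(self.segment_sets(chrom, s, e, eff))
        if mode == "union":
            genes = frozenset().union(*sets) if sets else frozenset()
        elif mode == "intersection-strict":
            genes = reduce(frozenset.__and__, sets) if sets else frozenset()
        else:
            nonempty = [x for x in sets if x]
            genes = (
                reduce(frozenset.__and__, nonempty) if nonempty else frozenset()
            )
        if not genes:
            return "__no_feature"
        if len(genes) == 1:
            return next(iter(genes))
        return "__ambiguous"


# ---------------------------------------------------------------------------
# generation


def _cigar_for_blocks(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def _read_seq(
    genome: dict[str, str],
    chrom: str,
    blocks: list[tuple[int, int]],
    read_strand: str,
    rng: random.Random,
    error_rate: float,
) -> str:
    seq = "".join(genome[chrom][s:e] for s, e in blocks)
    if read_strand == "-":
        seq = reverse_complement(seq)
    if error_rate > 0:
        chars = list(seq)
        for i, c in enumerate(chars):
            if rng.random() < error_rate:
                chars[i] = rng.choice("ACGT".replace(c, "") or "N")
        seq = "".join(chars)
    return seq


def _qual_str(rng: random.Random, n: int) -> str:
    return "".join(chr(rng.randint(30, 40) + 33) for _ in range(n))


def generate(spec: FixtureSpec) -> FixtureResult:
    """Generate the dataset and its ground truth; same seed, same bytes."""
    rng = random.Random(spec.seed)
    genes = _place_genes(spec, rng)
    genome = {
        f"chr{i + 1}": "".join(
            rng.choice("ACGT") for _ in range(spec.chrom_len)
        )
        for i in range(spec.n_chroms)
    }
    oracle = _TruthOracle(genes)
    gene_ids = [g.gene_id for g in genes]

    combos = [(m, s) for m in MODES for s in STRANDED]
    tallies: dict[str, dict[str, int]] = {
        f"{m}|{s}": {g: 0 for g in gene_ids} for m, s in combos
    }
    for t in tallies.values():
        for sp in (
            "__no_feature",
            "__ambiguous",
            "__too_low_aQual",
            "__not_aligned",
            "__alignment_not_unique",
        ):
            t[sp] = 0

    sam_lines: list[str] = []
    n_units = 0

    def emit_special(label: str, units: int = 1) -> None:
        nonlocal n_units
        for t in tallies.values():
            t[label] += units
        n_units += units

    def emit_oracle(mates) -> None:
        nonlocal n_units
        for m, s in combos:
            tallies[f"{m}|{s}"][oracle.assign(mates, m, s)] += 1
        n_units += 1

    def sam_pair(
        name: str,
        chrom: str,
        b1: list[tuple[int, int]],
        strand1: str,
        b2: list[tuple[int, int]],
        strand2: str,
        mapq: int,
        extra_flag: int = 0,
        tags: tuple[str, ...] = (),
    ) -> None:
        pos1, pos2 = b1[0][0], b2[0][0]
        outer = max(b1[-1][1], b2[-1][1]) - min(pos1, pos2)
        tl1 = outer if pos1 <= pos2 else -outer
        for role_flag, own_b, own_strand, other_b, other_strand, tl in (
            (0x40, b1, strand1, b2, strand2, tl1),
            (0x80, b2, strand2, b1, strand1, -tl1),
        ):
            flag = 0x1 | 0x2 | role_flag | extra_flag
            if own_strand == "-":
                flag |= 0x10
            if other_strand == "-":
                flag |= 0x20
            seq = _read_seq(
                genome, chrom, own_b, own_strand, rng, spec.error_rate
            )
            fields = [
                name,
                str(flag),
                chrom,
                str(own_b[0][0] + 1),
                str(mapq),
                _cigar_for_blocks(own_b),
                "=",
                str(other_b[0][0] + 1),
                str(tl),
                seq,
                _qual_str(rng, len(seq)),
            ]
            fields.extend(tags)
            sam_lines.append("\t".join(fields))

    def sam_single(
        name: str,
        chrom: str,
        blocks: list[tuple[int, int]],
        strand: str,
        mapq: int,
        extra_flag: int = 0,
        tags: tuple[str, ...] = (),
    ) -> None:
        flag = extra_flag | (0x10 if strand == "-" else 0)
        seq = _read_seq(genome, chrom, blocks, strand, rng, spec.error_rate)
        fields = [
            name,
            str(flag),
            chrom,
            str(blocks[0][0] + 1),
            str(mapq),
            _cigar_for_blocks(blocks),
            "*",
            "0",
            "0",
            seq,
            _qual_str(rng, len(seq)),
        ]
        fields.extend(tags)
        sam_lines.append("\t".join(fields))

    def random_read_record(name: str, flag: int) -> str:
        seq = "".join(rng.choice("ACGT") for _ in range(spec.read_len))
        return "\t".join(
            [
                name,
                str(flag),
                "*",
                "0",
                "0",
                "*",
                "*",
                "0",
                "0",
                seq,
                _qual_str(rng, spec.read_len),
            ]
        )

    def sample_fragment(gene: _Gene):
        """Transcript-space fragment -> per-mate genomic blocks."""
        L = gene.transcript_len
        min_flen = 2 * spec.read_len if spec.paired else spec.read_len
        max_flen = min(L, min_flen + 150)
        flen = rng.randint(min_flen, max_flen)
        f0 = rng.randint(0, L - flen)
        b1 = _transcript_to_blocks(gene, f0, f0 + spec.read_len)
        if not spec.paired:
            return b1, None
        b2 = _transcript_to_blocks(
            gene, f0 + flen - spec.read_len, f0 + flen
        )
        return b1, b2

    def decoy_position(flen: int) -> tuple[str, int]:
        chrom = rng.choice(sorted(genome))
        lo = spec.chrom_len - _TAIL_ZONE + 100
        hi = spec.chrom_len - 100 - flen
        return chrom, rng.randint(lo, hi)

    p_un = spec.unaligned_fraction
    p_mm = p_un + spec.multimap_fraction
    p_nf = p_mm + spec.nofeature_fraction

    for i in range(spec.n_fragments):
        name = f"frag{i:06d}"
        draw = rng.random()
        if draw < p_un:
            if spec.paired:
                sam_lines.append(
                    random_read_record(name, 0x1 | 0x4 | 0x8 | 0x40)
                )
                sam_lines.append(
                    random_read_record(name, 0x1 | 0x4 | 0x8 | 0x80)
                )
            else:
                sam_lines.append(random_read_record(name, 0x4))
            emit_special("__not_aligned")
        elif draw < p_mm:
            gene = rng.choice(genes)
            b1, b2 = sample_fragment(gene)
            span = (
                (max(b1[-1][1], b2[-1][1]) - min(b1[0][0], b2[0][0]))
                if b2
                else (b1[-1][1] - b1[0][0])
            )
            dchrom, dpos = decoy_position(span)
            shift = dpos - min(b1[0][0], b2[0][0] if b2 else b1[0][0])
            d1 = [(s + shift, e + shift) for s, e in b1]
            tags = ("NH:i:2",)
            if spec.paired:
                assert b2 is not None
                d2 = [(s + shift, e + shift) for s, e in b2]
                sam_pair(
                    name, gene.chrom, b1, gene.strand, b2,
                    flip_strand(gene.strand), 3, 0, tags,
                )
                sam_pair(
                    name, dchrom, d1, gene.strand, d2,
                    flip_strand(gene.strand), 0, 0x100, tags,
                )
                emit_special("__alignment_not_unique", units=2)
            else:
                sam_single(name, gene.chrom, b1, gene.strand, 3, 0, tags)
                sam_single(name, dchrom, d1, gene.strand, 0, 0x100, tags)
                emit_special("__alignment_not_unique", units=2)
        elif draw < p_nf:
            chrom = rng.choice(sorted(genome))
            strand = rng.choice("+-")
            if spec.paired:
                flen = 2 * spec.read_len + rng.randint(0, 100)
                lo = spec.chrom_len - _TAIL_ZONE + 100
                hi = spec.chrom_len - 100 - flen
                start = rng.randint(lo, hi)
                b1 = [(start, start + spec.read_len)]
                b2 = [(start + flen - spec.read_len, start + flen)]
                sam_pair(
                    name, chrom, b1, strand, b2, flip_strand(strand), 50
                )
                emit_oracle(
                    [
                        (chrom, b1, strand, "first"),
                        (chrom, b2, flip_strand(strand), "second"),
                    ]
                )
            else:
                lo = spec.chrom_len - _TAIL_ZONE + 100
                hi = spec.chrom_len - 100 - spec.read_len
                start = rng.randint(lo, hi)
                b1 = [(start, start + spec.read_len)]
                sam_single(name, chrom, b1, strand, 50)
                emit_oracle([(chrom, b1, strand, "single")])
        else:
            gene = rng.choice(genes)
            b1, b2 = sample_fragment(gene)
            if spec.paired:
                assert b2 is not None
                sam_pair(
                    name, gene.chrom, b1, gene.strand, b2,
                    flip_strand(gene.strand), 50,
                )
                emit_oracle(
                    [
                        (gene.chrom, b1, gene.strand, "first"),
                        (gene.chrom, b2, flip_strand(gene.strand), "second"),
                    ]
                )
            else:
                sam_single(name, gene.chrom, b1, gene.strand, 50)
                emit_oracle([(gene.chrom, b1, gene.strand, "single")])

    # -- serialize --------------------------------------------------------

    fasta_parts = []
    for chrom in sorted(genome):
        fasta_parts.append(f">{chrom}")
        seq = genome[chrom]
        fasta_parts.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
    fasta = "\n".join(fasta_parts) + "\n"

    gtf_lines = []
    for gene in genes:
        attr = f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.1";'
        gtf_lines.append(
            "\t".join(
                [
                    gene.chrom, "fixture", "gene", str(gene.start + 1),
                    str(gene.end), ".", gene.strand, ".",
                    f'gene_id "{gene.gene_id}";',
                ]
            )
        )
        for s, e in gene.exons:
            gtf_lines.append(
                "\t".join(
                    [
                        gene.chrom, "fixture", "exon", str(s + 1), str(e),
                        ".", gene.strand, ".", attr,
                    ]
                )
            )
    gtf = "\n".join(gtf_lines) + "\n"

    header = ["@HD\tVN:1.6\tSO:unsorted"]
    header.extend(
        f"@SQ\tSN:{chrom}\tLN:{spec.chrom_len}" for chrom in sorted(genome)
    )
    sam = "\n".join(header + sam_lines) + "\n"

    truth = FixtureTruth(gene_ids=gene_ids, n_units=n_units, counts=tallies)
    return FixtureResult(
        spec=spec, fasta=fasta, gtf=gtf, sam=sam, truth=truth, genes=genes
    )
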
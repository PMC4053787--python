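"""SNP/small-indel hard-filter cascade and validation bookkeeping.

In a comparison of two inbred sub-strains every true variant should be
homozygous, so calls with a low alternate-allele ratio are heterozygous
artifacts, and calls at extreme read depth sit in collapsed repeats or
dropout regions.  The cascade therefore: (1) subtracts calls shared with an
independent re-sequencing of the reference strain (reference discrepancies,
not sub-strain differences); (2) removes calls with allele ratio < 0.8 or
depth < 3 or > 150 — the boundary values themselves pass.  Retained coding
calls are classified against transcript models, checked for privacy against
a panel of other inbred strains, and finally adjudicated by a genotyping
panel of four samples per sub-strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

Genotype = tuple[str, str] | None  # diploid call, None = assay failure

CONSEQUENCES = (
    "missense",
    "nonsense",
    "synonymous",
    "splice",
    "frameshift",
    "inframe_indel",
    "noncoding",
)

#: intronic bases flanking a coding exon that disrupt splicing (canonical
#: donor/acceptor dinucleotides)
SPLICE_WINDOW = 2


@dataclass(frozen=True)
class VariantCall:
    """One called site with its read support."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int = 0
    allele_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"negative depth at {self.chrom}:{self.pos}")
        if not 0.0 <= self.allele_ratio <= 1.0:
            raise ValueError(f"allele ratio outside [0,1] at {self.chrom}:{self.pos}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def key(self) -> tuple[str, int, str, str]:
        """Identity key (chrom, pos, ref, alt) after minimal-representation
        trimming, so differently padded spellings of one indel match."""
        pos, ref, alt = self.pos, self.ref, self.alt
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        return (self.chrom, pos, ref, alt)


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter cutoffs; strict inequalities, boundaries pass."""

    min_allele_ratio: float = 0.8
    min_depth: int = 3
    max_depth: int = 150

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth exceeds max_depth")
        if not 0.0 < self.min_allele_ratio <= 1.0:
            raise ValueError("min_allele_ratio must be in (0, 1]")


def left_normalize(call: VariantCall, ref_seq: str) -> VariantCall:
    """Shift an indel to its smallest start producing an identical haplotype.

    *ref_seq* is the full chromosome sequence (1-based positions index into
    it).  SNVs and already-normalized calls are returned unchanged.
    """
    chrom, pos, ref, alt = call.key()
    if len(ref) == len(alt):
        return call
    # reduce to anchored form: one allele is a prefix of the other
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    longer, shorter = (ref, alt) if len(ref) > len(alt) else (alt, ref)
    if not longer.startswith(shorter):
        return VariantCall(chrom, pos, ref, alt, call.depth, call.allele_ratio)
    # shift left while the base entering from the left equals the base
    # leaving on the right of the inserted/deleted unit
    unit = longer[len(shorter):]
    while pos > 1 and ref_seq[pos - 2].upper() == unit[-1].upper():
        prev = ref_seq[pos - 2].upper()
        unit = prev + unit[:-1]
        pos -= 1
        anchor = ref_seq[pos - 1].upper()
        if len(ref) > len(alt):
            ref, alt = anchor + unit, anchor
        else:
            ref, alt = anchor, anchor + unit
    return VariantCall(chrom, pos, ref, alt, call.depth, call.allele_ratio)


def subtract_reference_calls(
    focal: Sequence[VariantCall], reference: Sequence[VariantCall]
) -> list[VariantCall]:
    """Drop focal calls whose (chrom, pos, ref, alt) key also appears in the
    independent reference call set; order preserved, duplicates within the
    focal set warn and keep the first."""
    ref_keys = {c.key() for c in reference}
    seen: set[tuple] = set()
    out = []
    for call in focal:
        k = call.key()
        if k in seen:
            warnings.warn(f"duplicate focal call at {k[0]}:{k[1]}, first kept")
            continue
        seen.add(k)
        if k not in ref_keys:
            out.append(call)
    return out


def apply_quality_filters(
    calls: Sequence[VariantCall], thresholds: FilterThresholds = FilterThresholds()
) -> tuple[list[VariantCall], list[tuple[VariantCall, str]]]:
    """Split calls into (retained, removed-with-reason).

    A call is removed iff allele_ratio < min_allele_ratio (reason
    ``heterozygous``) or depth outside [min_depth, max_depth] (reason
    ``low_depth`` / ``high_depth``); the allele-ratio check takes
    precedence so each removal carries its first failing reason.
    """
    retained, removed = [], []
    for call in calls:
        if call.allele_ratio < thresholds.min_allele_ratio:
            removed.append((call, "heterozygous"))
        elif call.depth < thresholds.min_depth:
            removed.append((call, "low_depth"))
        elif call.depth > thresholds.max_depth:
            removed.append((call, "high_depth"))
        else:
            retained.append(call)
    return retained, removed


# ---------------------------------------------------------------------------
# consequence classification


@dataclass(frozen=True)
class TranscriptModel:
    """Minimal transcript: exon structure plus the spliced CDS sequence.

    Exons are 1-based inclusive genomic intervals in ascending order.
    ``cds_start``/``cds_end`` delimit the translated span in genomic
    coordinates; ``cds_sequence`` is the spliced CDS on the coding strand,
    5'→3', length divisible by 3.
    """

    gene: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    cds_sequence: str

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s1 > e1 or s2 > e2 or e1 >= s2:
                raise ValueError(f"{self.gene}: exons must be ordered, non-overlapping")
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length not divisible by 3")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in coding (translation) order."""
        pos = [
            p
            for s, e in self.exons
            for p in range(max(s, self.cds_start), min(e, self.cds_end) + 1)
        ]
        return pos[::-1] if self.strand == "-" else pos

    def splice_sites(self) -> set[int]:
        """Intronic positions within SPLICE_WINDOW of a coding exon edge."""
        sites: set[int] = set()
        coding = [
            (s, e)
            for s, e in self.exons
            if min(e, self.cds_end) >= max(s, self.cds_start)
        ]
        first_start, last_end = self.exons[0][0], self.exons[-1][1]
        for s, e in coding:
            if s != first_start:
                sites.update(range(s - SPLICE_WINDOW, s))
            if e != last_end:
                sites.update(range(e + 1, e + 1 + SPLICE_WINDOW))
        return sites


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def classify_consequence(v: VariantCall, tm: TranscriptModel) -> str:
    """Predict the coding consequence of *v* on transcript *tm*.

    SNVs inside the CDS are translated codon-wise (strand-aware): a gained
    stop is ``nonsense``, an amino-acid change ``missense``, otherwise
    ``synonymous``.  Variants touching the 2 intronic bases flanking a
    coding exon are ``splice``.  CDS indels are ``frameshift`` when the
    length change is not a multiple of 3, else ``inframe_indel``.  Anything
    else — including positions outside the transcript span — is
    ``noncoding``.
    """
    if v.chrom != tm.chrom:
        raise ValueError(f"variant on {v.chrom} vs transcript on {tm.chrom}")
    if not v.ref or not v.alt or any(
        b not in "ACGTacgt" for b in v.ref + v.alt if b != "-"
    ):
        raise ValueError(f"malformed alleles {v.ref!r}>{v.alt!r}")

    # positions whose base actually changes: the whole ref span for an SNV,
    # the deleted bases (past the anchor) for a deletion, the two bases
    # flanking the insertion point for an insertion
    if not v.is_indel:
        affected: tuple[int, ...] = tuple(range(v.pos, v.pos + len(v.ref)))
    elif len(v.ref) > len(v.alt):
        affected = tuple(range(v.pos + 1, v.pos + len(v.ref)))
    else:
        affected = (v.pos, v.pos + 1)
    cds_order = tm.cds_positions()
    cds_index = {p: i for i, p in enumerate(cds_order)}

    if not v.is_indel and len(v.ref) == 1 and v.pos in cds_index:
        i = cds_index[v.pos]
        ref_base, alt_base = v.ref.upper(), v.alt.upper()
        if tm.strand == "-":
            ref_base = ref_base.translate(_COMPLEMENT)
            alt_base = alt_base.translate(_COMPLEMENT)
        if tm.cds_sequence[i].upper() != ref_base:
            raise ValueError(
                f"reference allele mismatch at {v.chrom}:{v.pos} in {tm.gene}"
            )
        codon_i = i // 3
        codon = tm.cds_sequence[codon_i * 3 : codon_i * 3 + 3].upper()
        mutated = codon[: i % 3] + alt_base + codon[i % 3 + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mutated).translate())
        if aa_alt == "*" and aa_ref != "*":
            return "nonsense"
        return "missense" if aa_alt != aa_ref else "synonymous"

    splice_sites = tm.splice_sites()
    if any(p in splice_sites for p in affected):
        return "splice"

    if v.is_indel and any(p in cds_index for p in affected):
        return "frameshift" if abs(len(v.ref) - len(v.alt)) % 3 else "inframe_indel"

    return "noncoding"


def assess_privacy(
    v: VariantCall,
    panel: Mapping[str, Sequence[VariantCall]],
    carrier: str = "B6N",
) -> str:
    """Is the variant private to its carrier sub-strain, or shared?

    *panel* maps strain name to its call set.  Returns the carrier name
    when no panel strain carries the identical key, otherwise
    ``shared:<strain+strain...>``.
    """
    k = v.key()
    sharers = sorted(s for s, calls in panel.items() if k in {c.key() for c in calls})
    if sharers:
        return "shared:" + "+".join(sharers)
    return carrier


# ---------------------------------------------------------------------------
# validation assays

ASSAY_STATUSES = (
    "confirmed",
    "not_variant",
    "eliminated_heterozygous",
    "eliminated_inconsistent",
    "eliminated_pcr_failure",
)
PANEL_SIZE = 4


@dataclass
class ValidationAssay:
    """Genotyping of one candidate variant on a 4 B6J + 4 B6N panel."""

    variant_id: str
    platform: str  # sequenom | pyro | sanger
    genotypes_j: list[Genotype] = field(default_factory=list)
    genotypes_n: list[Genotype] = field(default_factory=list)
    coding: bool = False
    indel: bool = False
    status: str | None = None

    def __post_init__(self) -> None:
        if len(self.genotypes_j) != PANEL_SIZE or len(self.genotypes_n) != PANEL_SIZE:
            raise ValueError(
                f"assay {self.variant_id}: panel must be {PANEL_SIZE}+{PANEL_SIZE}"
            )


def adjudicate_assay(a: ValidationAssay) -> str:
    """Assign the validation status of one assay.

    Precedence: any missing call → PCR failure; any heterozygous call →
    heterozygous; within-strain disagreement → inconsistent; both strains
    homozygous for the same allele → not a variant; otherwise confirmed
    (consistent within each sub-strain, different between them).
    """
    calls = a.genotypes_j + a.genotypes_n
    if any(g is None for g in calls):
        status = "eliminated_pcr_failure"
    elif any(g[0] != g[1] for g in calls):
        status = "eliminated_heterozygous"
    elif len(set(a.genotypes_j)) > 1 or len(set(a.genotypes_n)) > 1:
        status = "eliminated_inconsistent"
    elif a.genotypes_j[0] == a.genotypes_n[0]:
        status = "not_variant"
    else:
        status = "confirmed"
    a.status = status
    return status


def summarize_validation(assays: Sequence[ValidationAssay]) -> dict:
    """Ledger summary over adjudicated assays.

    remaining = assayed − eliminated; confirmed broken down by
    coding/non-coding × SNP/indel.
    """
    for a in assays:
        if a.status is None:
            raise ValueError(f"assay {a.variant_id} not adjudicated")
    by_status = {s: sum(1 for a in assays if a.status == s) for s in ASSAY_STATUSES}
    eliminated = sum(v for s, v in by_status.items() if s.startswith("eliminated"))
    confirmed = [a for a in assays if a.status == "confirmed"]
    category = {
        "coding_snp": sum(1 for a in confirmed if a.coding and not a.indel),
        "coding_indel": sum(1 for a in confirmed if a.coding and a.indel),
        "noncoding_snp": sum(1 for a in confirmed if not a.coding and not a.indel),
        "noncoding_indel": sum(1 for a in confirmed if not a.coding and a.indel),
    }
    return {
        "assayed": len(assays),
        "eliminated": eliminated,
        "remaining": len(assays) - eliminated,
        "by_status": by_status,
        "confirmed": by_status["confirmed"],
        "confirmed_by_category": category,
    }


# ---------------------------------------------------------------------------
# optional manual-curation rule (defaults off in the cascade)


def curation_flags(
    call: VariantCall,
    chrom_seq: str,
    homopolymer_min: int = 8,
    gc_window: int = 50,
    gc_max: float = 0.8,
) -> list[str]:
    """Sequence-context reasons to drop a call during manual curation:
    inside a homopolymer run of ``homopolymer_min`` or longer, or in a
    ``gc_window``-bp window with GC fraction above ``gc_max``."""
    flags = []
    i = call.pos - 1
    seq = chrom_seq.upper()
    base = seq[i]
    run = 1
    j = i - 1
    while j >= 0 and seq[j] == base:
        run += 1
        j -= 1
    j = i + 1
    while j < len(seq) and seq[j] == base:
        run += 1
        j += 1
    if run >= homopolymer_min:
        flags.append("homopolymer")
    lo = max(0, i - gc_window // 2)
    window = seq[lo : lo + gc_window]
    if window and (window.count("G") + window.count("C")) / len(window) > gc_max:
        flags.append("gc_rich")
    return flags


# ---------------------------------------------------------------------------
# I/O: minimal VCF with DP/AR, the TSV dialect, BED12 transcripts

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AR,Number=1,Type=Float,Description="Alternate allele ratio">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Iterable[VariantCall], path: str | Path) -> Path:
    """Write calls as a minimal VCF v4.2 with DP and AR INFO keys."""
    calls = list(calls)
    contigs = "".join(
        f"##contig=<ID={c}>\n" for c in dict.fromkeys(c.chrom for c in calls)
    )
    lines = [_VCF_HEADER.format(contigs=contigs)]
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t.\t"
            f"DP={c.depth};AR={c.allele_ratio:g}\n"
        )
    path = Path(path)
    path.write_text("".join(lines))
    return path


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read a VCF with DP/AR INFO keys back into calls (via pysam)."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                out.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        depth=int(rec.info.get("DP", 0)),
                        allele_ratio=float(rec.info.get("AR", 1.0)),
                    )
                )
    return out


def read_calls_tsv(path: str | Path) -> list[VariantCall]:
    """Read the minimal TSV dialect: chrom, pos, ref, alt, depth, allele_ratio."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return [
        VariantCall(r.chrom, int(r.pos), r.ref, r.alt, int(r.depth), float(r.allele_ratio))
        for r in df.itertuples()
    ]


def write_calls_tsv(calls: Iterable[VariantCall], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("chrom\tpos\tref\talt\tdepth\tallele_ratio\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.depth}\t{c.allele_ratio:g}\n"
            )
    return path


def transcripts_from_bed12(
    bed_path: str | Path, fasta: Mapping[str, str]
) -> list[TranscriptModel]:
    """Build transcript models from a BED12 file plus chromosome sequences.

    *fasta* maps chromosome name to sequence (a pyfaidx.Fasta works).  The
    BED name field is taken as the gene symbol; thickStart/thickEnd delimit
    the CDS.
    """
    models = []
    for line in Path(bed_path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        chrom, start0, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        thick_start0, thick_end = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = tuple(
            (start0 + off + 1, start0 + off + size) for off, size in zip(offsets, sizes)
        )
        if exons[-1][1] != end:
            raise ValueError(f"{name}: blocks do not span the BED interval")
        cds_start, cds_end = thick_start0 + 1, thick_end
        seq = str(fasta[chrom][:])
        cds = "".join(
            seq[max(s, cds_start) - 1 : min(e, cds_end)] for s, e in exons
        )
        if strand == "-":
            cds = cds.translate(_COMPLEMENT)[::-1]
        models.append(
            TranscriptModel(
                gene=name,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
                cds_sequence=cds.upper(),
            )
        )
    return models
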
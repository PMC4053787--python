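"""Packaged variant tables and validation bookkeeping.

The coding-variant table (36 records: 32 missense, 1 nonsense, 1 splice,
2 frameshift) and the structural-variant table (43 records) ship with the
package as plain TSV so every downstream stage is testable without any
download.  Loaders validate the tables on read and fail naming the
offending row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

CONSEQUENCE_CLASSES = ("missense", "nonsense", "splice", "frameshift")
OVERLAP_CLASSES = ("none", "intron", "exon", "entire")


class FixtureError(ValueError):
    """A packaged table failed validation on load."""


@dataclass(frozen=True)
class CodingVariantRecord:
    """One coding SNP or small indel distinguishing the sub-strains.

    ``private_to`` is ``B6J`` or ``B6N`` for private alleles and
    ``B6N_shared`` for the single variant (Zp2) also carried by another
    sequenced strain.  ``strain_label`` keeps the composite label as
    printed (e.g. ``B6N+Spretus``).  One record (Stxb4) prints a gene name
    in the amino-acid column; it is stored with ``aa_j`` missing and
    flagged ``as_printed_anomaly`` in ``note``.
    """

    chrom: str
    pos: int
    base_j: str
    base_n: str
    strain_label: str
    private_to: str
    gene: str
    consequence: str
    aa_j: str | None = None
    aa_n: str | None = None
    note: str | None = None

    @property
    def is_indel(self) -> bool:
        return self.base_j == "-" or self.base_n == "-"


@dataclass(frozen=True)
class SVRecord:
    """One structural variant, coordinates 1-based inclusive (NCBIM37).

    ``ancestral_event`` is the printed label ("LINE Ins", "Del (large)",
    "VNTR", ...); ``strain_primary`` is the parsed primary carrier of the
    derived allele, empty for the VNTR row which has no carrier.
    """

    chrom: str
    start: int
    stop: int
    ancestral_event: str
    strain_label: str
    strain_primary: str
    gene: str | None
    overlap: str

    @property
    def event_rollup(self) -> str:
        """Coarse event category: insertion / non_repeat / vntr."""
        if "VNTR" in self.ancestral_event:
            return "vntr"
        if "Ins" in self.ancestral_event:
            return "insertion"
        if "Del" in self.ancestral_event:
            return "non_repeat"
        raise FixtureError(f"unrecognized ancestral event {self.ancestral_event!r}")


@dataclass(frozen=True)
class ValidationSummary:
    """Seed counts for replaying the genotyping-validation ledger."""

    assayed_snps: int
    assayed_indels: int
    eliminated: int
    confirmed_by_category: dict[str, int] = field(default_factory=dict)

    @property
    def assayed_total(self) -> int:
        return self.assayed_snps + self.assayed_indels

    @property
    def remaining(self) -> int:
        return self.assayed_total - self.eliminated

    @property
    def confirmed_total(self) -> int:
        return sum(self.confirmed_by_category.values())


def _data_path(name: str) -> Path:
    return Path(str(resources.files("b6compare").joinpath("data", name)))


def _read_fixture(name: str) -> pd.DataFrame:
    df = pd.read_csv(_data_path(name), sep="\t", comment="#", dtype=str)
    return df.fillna("")


def load_coding_variant_table() -> list[CodingVariantRecord]:
    """Load the 36 packaged coding SNP/indel records."""
    df = _read_fixture("coding_variants.tsv")
    records = []
    for i, row in df.iterrows():
        try:
            rec = CodingVariantRecord(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                base_j=row["base_j"],
                base_n=row["base_n"],
                strain_label=row["strain_label"],
                private_to=row["private_to"],
                gene=row["gene"],
                consequence=row["consequence"],
                aa_j=row["aa_j"] or None,
                aa_n=row["aa_n"] or None,
                note=row["note"] or None,
            )
            if rec.pos < 1:
                raise ValueError(f"non-positive position {rec.pos}")
            if rec.consequence not in CONSEQUENCE_CLASSES:
                raise ValueError(f"unknown consequence {rec.consequence!r}")
        except (KeyError, ValueError) as exc:
            raise FixtureError(f"coding_variants.tsv row {i + 1}: {exc}") from exc
        records.append(rec)
    if len(records) != 36:
        raise FixtureError(f"expected 36 coding variant records, got {len(records)}")
    shared = [r for r in records if r.private_to == "B6N_shared"]
    if [r.gene for r in shared] != ["Zp2"]:
        raise FixtureError("exactly one record (Zp2) must be B6N_shared")
    return records


def load_sv_table() -> list[SVRecord]:
    """Load the 43 packaged structural-variant records."""
    df = _read_fixture("structural_variants.tsv")
    records = []
    for i, row in df.iterrows():
        try:
            rec = SVRecord(
                chrom=row["chrom"],
                start=int(row["start"]),
                stop=int(row["stop"]),
                ancestral_event=row["ancestral_event"],
                strain_label=row["strain_label"],
                strain_primary=row["strain_primary"],
                gene=row["gene"] or None,
                overlap=row["overlap"],
            )
            if rec.start > rec.stop:
                raise ValueError(f"start {rec.start} > stop {rec.stop}")
            if rec.overlap not in OVERLAP_CLASSES:
                raise ValueError(f"unknown overlap {rec.overlap!r}")
            if (rec.overlap == "none") != (rec.gene is None):
                raise ValueError("overlap must be 'none' exactly when no gene is named")
            rec.event_rollup  # validates the event label
        except (KeyError, ValueError) as exc:
            raise FixtureError(f"structural_variants.tsv row {i + 1}: {exc}") from exc
        records.append(rec)
    if len(records) != 43:
        raise FixtureError(f"expected 43 SV records, got {len(records)}")
    return records


def load_validation_summary() -> ValidationSummary:
    """Load the genotyping-campaign bookkeeping counts."""
    df = _read_fixture("validation_summary.tsv")
    counts = {row["field"]: int(row["count"]) for _, row in df.iterrows()}
    try:
        return ValidationSummary(
            assayed_snps=counts["assayed_snps"],
            assayed_indels=counts["assayed_indels"],
            eliminated=counts["eliminated"],
            confirmed_by_category={
                "coding_snp": counts["confirmed_coding_snps"],
                "coding_indel": counts["confirmed_coding_indels"],
                "noncoding_snp": counts["confirmed_noncoding_snps"],
                "noncoding_indel": counts["confirmed_noncoding_indels"],
            },
        )
    except KeyError as exc:
        raise FixtureError(f"validation_summary.tsv missing field {exc}") from exc


def export_fixture(name: str, dest: str | Path) -> Path:
    """Copy a packaged fixture TSV (``coding_variants``, ``structural_variants``
    or ``validation_summary``) to *dest* and return the written path."""
    src = _data_path(f"{name}.tsv")
    if not src.exists():
        raise FixtureError(f"no packaged fixture named {name!r}")
    dest = Path(dest)
    if dest.is_dir():
        dest = dest / src.name
    dest.write_text(src.read_text())
    return dest
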
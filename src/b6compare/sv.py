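"""Structural-variant triage ledger.

Candidate SVs come from multiple detection methods; calls of the same type
with sufficient reciprocal overlap are merged into one candidate.  Each
candidate then moves through an audited state machine:

    predicted ──> false_pe_error      (visual inspection: paired-end
              └─> retained             mapping artifact)
    retained  ──> reference_error     (PCR/Sanger: not polymorphic,
              └─> validated            reference assembly error)

No verdict sequence can reach ``validated`` without passing ``retained``.
Validated candidates are annotated with gene overlap (entire > exon >
intron severity when several genes are hit) and an ancestral event
inferred against an outgroup: the derived allele is the one absent from
the outgroup, so a derived gain of repeat-matching sequence is a
retrotransposition, a derived loss a deletion, and a copy-number change of
a tandem array a VNTR difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

SV_TYPES = ("insertion", "deletion", "tandem_repeat")
STATES = ("predicted", "false_pe_error", "retained", "reference_error", "validated")
TRANSITIONS = {
    "predicted": {"false_pe_error", "retained"},
    "retained": {"reference_error", "validated"},
}
RETRO_CLASSES = ("LINE", "SINE", "IAP", "MaLR", "MTA")
_OVERLAP_SEVERITY = {"entire": 3, "exon": 2, "intron": 1, "none": 0}


class TransitionError(ValueError):
    """An SV verdict violates the triage state machine."""


@dataclass
class SVCandidate:
    """One merged SV candidate with its triage state.

    Coordinates are 1-based inclusive; insertions are zero-extent on the
    reference (start == stop printed conventions of start, start+1 are
    normalized by the caller) with the inserted length in ``ins_length``.
    """

    id: str
    chrom: str
    start: int
    stop: int
    svtype: str
    repeat_class: str = "none"
    supporting_methods: frozenset[str] = field(default_factory=frozenset)
    state: str = "predicted"
    derived_in: str = ""
    overlap: str = "none"
    gene: str | None = None
    ancestral_event: str = ""
    ins_length: int = 0

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(f"{self.id}: start > stop")
        if self.svtype not in SV_TYPES:
            raise ValueError(f"{self.id}: unknown svtype {self.svtype!r}")
        if self.state not in STATES:
            raise ValueError(f"{self.id}: unknown state {self.state!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene's transcribed span and exon structure (1-based inclusive)."""

    gene: str
    chrom: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*self.exons)
        return (min(starts), max(ends))


@dataclass(frozen=True)
class OutgroupEvidence:
    """Presence of each SV allele in the outgroup species.

    ``with_seq_present`` refers to the allele carrying the extra sequence,
    ``without_seq_present`` to the shorter allele.  At least one allele
    must be ancestral (present).
    """

    with_seq_present: bool
    without_seq_present: bool

    def __post_init__(self) -> None:
        if not (self.with_seq_present or self.without_seq_present):
            raise ValueError("at least one allele must be present in the outgroup")


def _length(start: int, stop: int) -> int:
    return stop - start + 1


def _reciprocal_overlap(a: SVCandidate, b: SVCandidate) -> float:
    ov = min(a.stop, b.stop) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / _length(a.start, a.stop), ov / _length(b.start, b.stop))


def merge_candidates(
    method_calls: Mapping[str, Sequence[SVCandidate]],
    reciprocal_overlap: float = 0.5,
) -> list[SVCandidate]:
    """Merge per-method call lists into unified predicted candidates.

    Calls of the same type on the same chromosome whose reciprocal overlap
    meets the threshold collapse into one candidate spanning their union,
    accumulating the supporting method labels.  Idempotent: merging an
    already-merged list changes nothing.
    """
    if not 0 < reciprocal_overlap <= 1:
        raise ValueError("reciprocal_overlap must be in (0, 1]")
    pool: list[SVCandidate] = []
    for method, calls in method_calls.items():
        for c in calls:
            methods = c.supporting_methods or frozenset({method})
            pool.append(replace(c, supporting_methods=methods))
    pool.sort(key=lambda c: (c.chrom, c.start, c.stop, c.svtype))

    merged: list[SVCandidate] = []
    for call in pool:
        target = None
        for cand in merged:
            if cand.chrom == call.chrom and cand.svtype == call.svtype:
                if _reciprocal_overlap(cand, call) >= reciprocal_overlap:
                    target = cand
                    break
        if target is None:
            merged.append(replace(call, state="predicted"))
        else:
            target.start = min(target.start, call.start)
            target.stop = max(target.stop, call.stop)
            target.supporting_methods = target.supporting_methods | call.supporting_methods
    for i, cand in enumerate(merged):
        cand.id = cand.id or f"sv{i:04d}"
    return merged


def apply_triage_verdicts(
    candidates: Sequence[SVCandidate], verdicts: Mapping[str, str]
) -> dict[str, int]:
    """Apply per-candidate verdicts, enforcing the transition graph.

    Returns the count of candidates per state after the update.  An
    illegal transition (e.g. predicted → validated) raises
    :class:`TransitionError` naming the candidate.
    """
    by_id = {c.id: c for c in candidates}
    for cid, verdict in verdicts.items():
        if cid not in by_id:
            raise KeyError(f"unknown candidate {cid!r}")
        cand = by_id[cid]
        allowed = TRANSITIONS.get(cand.state, set())
        if verdict not in allowed:
            raise TransitionError(
                f"candidate {cid}: illegal transition {cand.state} -> {verdict}"
            )
        cand.state = verdict
    return {s: sum(1 for c in candidates if c.state == s) for s in STATES}


def annotate_gene_overlap(
    sv: SVCandidate, genes: Iterable[GeneModel]
) -> tuple[str, str | None]:
    """Label the SV's gene overlap and record it on the candidate.

    entire — the SV contains the gene's whole transcribed span; exon — it
    intersects at least one exon base; intron — it intersects the gene
    span without touching an exon.  With several genes hit, the most
    severe label wins (entire > exon > intron).  Insensitive to gene
    strand and exon ordering.
    """
    best = ("none", None)
    for g in genes:
        if g.chrom != sv.chrom:
            continue
        g_start, g_end = g.span
        if sv.stop < g_start or sv.start > g_end:
            continue
        if sv.start <= g_start and sv.stop >= g_end:
            label = "entire"
        elif any(sv.start <= e and sv.stop >= s for s, e in g.exons):
            label = "exon"
        else:
            label = "intron"
        if _OVERLAP_SEVERITY[label] > _OVERLAP_SEVERITY[best[0]]:
            best = (label, g.gene)
    sv.overlap, sv.gene = best
    return best


def classify_ancestral_event(
    sv: SVCandidate, og: OutgroupEvidence, repeat_class: str = "none"
) -> tuple[str, str]:
    """Infer the mutational event from outgroup presence.

    Returns ``(label, rollup)`` and records the label on the candidate:
    a derived gain matching a mobile-element class is a retrotransposition
    ("LINE Ins", ...; rollup ``insertion``), a plain gain "Ins" (same
    rollup), a derived loss "Del" (rollup ``non_repeat``), and a tandem
    array copy-number change "VNTR" (rollup ``vntr``).
    """
    if sv.svtype == "tandem_repeat":
        sv.ancestral_event = "VNTR"
        return "VNTR", "vntr"
    if og.with_seq_present and og.without_seq_present:
        raise ValueError(f"{sv.id}: both alleles outgroup-present, event ambiguous")
    derived_gain = not og.with_seq_present  # the with-sequence allele is derived
    if derived_gain:
        label = f"{repeat_class} Ins" if repeat_class in RETRO_CLASSES else "Ins"
        rollup = "insertion"
    else:
        label, rollup = "Del", "non_repeat"
    sv.ancestral_event = label
    return label, rollup


def _rollup(event: str) -> str:
    if "VNTR" in event:
        return "vntr"
    if "Ins" in event:
        return "insertion"
    if "Del" in event:
        return "non_repeat"
    raise ValueError(f"unrecognized ancestral event {event!r}")


def summarize_svs(items: Sequence) -> dict:
    """Tally a set of SV candidates or fixture records.

    Accepts anything with ``overlap`` and ``ancestral_event`` attributes
    (and optionally ``state`` / strain labels); tallies are additive and
    exhaustive over the input.
    """
    out: dict[str, dict[str, int]] = {
        "by_overlap": {}, "by_rollup": {}, "by_strain": {}, "by_state": {},
    }

    def bump(table: str, key: str) -> None:
        out[table][key] = out[table].get(key, 0) + 1

    for it in items:
        bump("by_overlap", it.overlap)
        event = getattr(it, "ancestral_event", "")
        if event:
            bump("by_rollup", _rollup(event))
        strain = (getattr(it, "strain_primary", "") or
                  getattr(it, "derived_in", "") or "unassigned")
        bump("by_strain", strain)
        if hasattr(it, "state"):
            bump("by_state", it.state)
    out["total"] = len(items)
    out["gene_overlapping"] = sum(
        v for k, v in out["by_overlap"].items() if k != "none"
    )
    return out
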
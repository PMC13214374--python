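"""Transcript-coordinate utilities for variant annotation and splicing.

Covers three recurring chores in the *CNGA1* variant literature:

* **TIS lifting** — the gene has been annotated against transcripts with
  different in-frame translation initiation sites (the MANE Select
  transcript encodes a 686-aa protein; a legacy transcript with a TIS
  12 bp further upstream encodes 690 aa), so protein positions and
  lengths shift by a fixed amino-acid offset between conventions.
* **Homology mapping** — assay controls are built by transplanting a
  residue between CNGA1 and CNGA3 through a pairwise protein alignment.
* **Splice-consequence prediction** — minigene assays reveal exon
  skipping and cryptic-acceptor usage; the coding-frame arithmetic
  (removed nucleotides mod 3) decides between an in-frame deletion and a
  frameshift with a predicted premature termination codon (PTC).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import UnsupportedCaseError, ValidationError

__all__ = [
    "Exon",
    "TranscriptModel",
    "TisOffset",
    "FrameStatus",
    "SpliceOutcome",
    "lift_protein_annotation",
    "map_homologous_residue",
    "predict_skipping_consequence",
    "predict_cryptic_acceptor_consequence",
    "load_domain_map",
    "synthetic_cnga1_model",
    "synthetic_cnga1_domains",
]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class Exon:
    label: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"exon {self.label}: length must be > 0")


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exons plus the CDS location on the spliced transcript.

    ``cds_start`` is the 0-based offset of the first coding base within
    the concatenated exonic sequence; ``cds_length`` includes the stop
    codon and must be divisible by 3.
    """

    transcript_id: str
    exons: tuple[Exon, ...]
    cds_start: int
    cds_length: int

    def __post_init__(self) -> None:
        if self.cds_start < 0 or self.cds_length <= 3:
            raise ValidationError("invalid CDS coordinates")
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3")
        if self.cds_start + self.cds_length > self.transcript_length:
            raise ValidationError(
                f"{self.transcript_id}: CDS extends beyond the spliced transcript")

    @property
    def transcript_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def protein_length_aa(self) -> int:
        return (self.cds_length - 3) // 3

    def exon_span(self, label: str) -> tuple[int, int]:
        """Half-open 0-based span of an exon on the spliced transcript."""
        pos = 0
        for e in self.exons:
            if e.label == label:
                return pos, pos + e.length
            pos += e.length
        raise ValidationError(f"{self.transcript_id}: no exon labelled {label!r}")

    def coding_overlap(self, label: str) -> int:
        """Nucleotides of an exon inside the CDS (stop codon included)."""
        start, end = self.exon_span(label)
        return max(0, min(end, self.cds_start + self.cds_length) - max(start, self.cds_start))

    @classmethod
    def from_exon_table(cls, table: pd.DataFrame | str | Path,
                        transcript_id: str = "custom") -> "TranscriptModel":
        """Build a model from a minimal TSV / frame with columns
        ``exon_label, length_nt, coding_overlap_nt``.

        The CDS is assumed contiguous: a 5' UTR prefix in the first coding
        exon and a 3' UTR suffix in the last.
        """
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t", dtype={"exon_label": str})
        required = {"exon_label", "length_nt", "coding_overlap_nt"}
        if missing := required - set(table.columns):
            raise ValidationError(f"exon table missing columns: {sorted(missing)}")
        exons = tuple(Exon(str(r.exon_label), int(r.length_nt))
                      for r in table.itertuples())
        overlaps = [int(v) for v in table["coding_overlap_nt"]]
        coding_idx = [i for i, v in enumerate(overlaps) if v > 0]
        if not coding_idx:
            raise ValidationError("exon table has no coding exons")
        first = coding_idx[0]
        for i in coding_idx[1:-1]:
            if overlaps[i] != exons[i].length:
                raise ValidationError(
                    f"internal coding exon {exons[i].label} is only partially "
                    "coding; the CDS must be contiguous")
        if coding_idx != list(range(first, coding_idx[-1] + 1)):
            raise ValidationError("coding exons must be contiguous")
        cds_start = sum(e.length for e in exons[:first]) + exons[first].length - overlaps[first]
        return cls(transcript_id=transcript_id, exons=exons,
                   cds_start=cds_start, cds_length=sum(overlaps))

    @classmethod
    def from_genbank(cls, source) -> "TranscriptModel":
        """Parse an mRNA GenBank record (e.g. a RefSeq NM_ accession).

        Exon features carry mRNA coordinates directly; the CDS feature
        gives the coding span. Falls back to a single pseudo-exon when no
        exon features are annotated.
        """
        from Bio import SeqIO  # deferred: only needed for this entry point

        record = source if hasattr(source, "features") else SeqIO.read(source, "genbank")
        cds = [f for f in record.features if f.type == "CDS"]
        if not cds:
            raise ValidationError(f"{record.id}: no CDS feature")
        cds_start = int(cds[0].location.start)
        cds_length = int(cds[0].location.end) - cds_start
        exon_feats = [f for f in record.features if f.type == "exon"]
        if exon_feats:
            exons = []
            for i, f in enumerate(exon_feats, start=1):
                label = f.qualifiers.get("number", [str(i)])[0]
                exons.append(Exon(str(label), int(f.location.end) - int(f.location.start)))
            exons = tuple(exons)
        else:
            exons = (Exon("1", len(record.seq)),)
        return cls(transcript_id=record.id, exons=exons,
                   cds_start=cds_start, cds_length=cds_length)


@dataclass(frozen=True)
class TisOffset:
    """In-frame offset between two translation-initiation-site conventions."""

    nucleotide_offset: int

    def __post_init__(self) -> None:
        if self.nucleotide_offset < 0 or self.nucleotide_offset % 3 != 0:
            raise ValidationError(
                f"TIS offset must be >= 0 and divisible by 3, "
                f"got {self.nucleotide_offset}")

    @property
    def aa_offset(self) -> int:
        return self.nucleotide_offset // 3


def lift_protein_annotation(position_or_length: int, offset: TisOffset,
                            direction: str) -> int:
    """Shift a protein position or length between TIS conventions.

    ``mane_to_legacy`` adds the amino-acid offset (the legacy protein is
    longer); ``legacy_to_mane`` subtracts it and errors for residues that
    do not exist in the shorter protein.
    """
    if direction == "mane_to_legacy":
        return position_or_length + offset.aa_offset
    if direction == "legacy_to_mane":
        lifted = position_or_length - offset.aa_offset
        if lifted < 1:
            raise ValidationError(
                f"position {position_or_length} lies within the first "
                f"{offset.aa_offset} residues absent from the shorter protein")
        return lifted
    raise ValidationError(f"unknown lift direction {direction!r}")


def map_homologous_residue(aligned_a: str, aligned_b: str, position_in_a: int,
                           ) -> tuple[int | None, bool | None]:
    """Map an ungapped residue position through a pairwise alignment.

    Returns ``(position_in_b, identical)`` where ``position_in_b`` is the
    1-based ungapped position in sequence b aligned to the same column, or
    ``None`` when b is gapped there (then ``identical`` is ``None`` too).
    ``identical`` reports whether the aligned residues match — the driver
    of homology-control design, where a non-identical residue is swapped
    to the other paralogue's wild-type residue.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("aligned sequences must have equal length")
    if position_in_a < 1:
        raise ValidationError("positions are 1-based")
    count_a = 0
    for col, (ca, cb) in enumerate(zip(aligned_a, aligned_b)):
        if ca not in GAP_CHARS:
            count_a += 1
            if count_a == position_in_a:
                if cb in GAP_CHARS:
                    return None, None
                pos_b = sum(1 for c in aligned_b[:col + 1] if c not in GAP_CHARS)
                return pos_b, ca.upper() == cb.upper()
    raise ValidationError(
        f"position {position_in_a} exceeds the ungapped length of sequence a")


class FrameStatus(str):
    IN_FRAME = "in_frame"
    FRAMESHIFT = "frameshift"


@dataclass(frozen=True)
class SpliceOutcome:
    """Predicted protein-level consequence of a missplicing event."""

    removed_coding_nt: int
    frame_status: str
    deleted_aa: int | None
    ptc_predicted: bool
    affected_domains: tuple[str, ...] = ()


def _domains_in(domain_map: pd.DataFrame | None, aa_start: int, aa_end: int,
                ) -> tuple[str, ...]:
    if domain_map is None or aa_end < aa_start:
        return ()
    hit = domain_map[(domain_map["aa_start"] <= aa_end)
                     & (domain_map["aa_end"] >= aa_start)]
    return tuple(hit["domain"])


def _consequence(model: TranscriptModel, removed_span: tuple[int, int],
                 domain_map: pd.DataFrame | None) -> SpliceOutcome:
    """Frame arithmetic for a removed transcript interval (half-open)."""
    cds_lo, cds_hi = model.cds_start, model.cds_start + model.cds_length
    lo = max(removed_span[0], cds_lo)
    hi = min(removed_span[1], cds_hi)
    removed = max(0, hi - lo)
    spans_stop = hi >= cds_hi - 3 and removed > 0
    if removed % 3 != 0:
        # downstream of the break, the reading frame is lost
        first_aa = (lo - cds_lo) // 3 + 1
        return SpliceOutcome(
            removed_coding_nt=removed, frame_status=FrameStatus.FRAMESHIFT,
            deleted_aa=None, ptc_predicted=True,
            affected_domains=_domains_in(domain_map, first_aa,
                                         model.protein_length_aa))
    deleted_aa = removed // 3
    first_aa = (lo - cds_lo) // 3 + 1
    return SpliceOutcome(
        removed_coding_nt=removed, frame_status=FrameStatus.IN_FRAME,
        deleted_aa=deleted_aa, ptc_predicted=spans_stop,
        affected_domains=_domains_in(domain_map, first_aa, first_aa + deleted_aa - 1))


def predict_skipping_consequence(model: TranscriptModel,
                                 skipped_exons: Sequence[str],
                                 domain_map: pd.DataFrame | None = None,
                                 ) -> SpliceOutcome:
    """Protein consequence of skipping internal coding exon(s).

    Skipping terminal exons proceeds by a different mechanism (promoter /
    polyadenylation effects) and is unsupported. The summed coding length
    of the skipped exons decides the frame: divisible by 3 means an
    in-frame deletion of length/3 residues, anything else a frameshift
    with a predicted PTC.
    """
    if not skipped_exons:
        raise ValidationError("no exons to skip")
    terminal = {model.exons[0].label, model.exons[-1].label}
    spans = []
    for label in skipped_exons:
        if label in terminal:
            raise UnsupportedCaseError(
                f"exon {label} is a terminal exon; skipping it is a "
                "different mechanism and is not modelled")
        if model.coding_overlap(label) == 0:
            raise ValidationError(f"exon {label} is non-coding")
        spans.append(model.exon_span(label))
    lo = min(s[0] for s in spans)
    hi = max(s[1] for s in spans)
    # skipped exons need not be adjacent in the model, but the removed
    # coding length is the sum of their individual overlaps
    removed = sum(model.coding_overlap(label) for label in skipped_exons)
    outcome = _consequence(model, (lo, hi), domain_map)
    if outcome.removed_coding_nt != removed:
        # non-adjacent skips: recompute frame on the true removed total
        spans_frame = removed % 3 == 0
        return SpliceOutcome(
            removed_coding_nt=removed,
            frame_status=FrameStatus.IN_FRAME if spans_frame else FrameStatus.FRAMESHIFT,
            deleted_aa=removed // 3 if spans_frame else None,
            ptc_predicted=not spans_frame,
            affected_domains=outcome.affected_domains)
    return outcome


def predict_cryptic_acceptor_consequence(model: TranscriptModel, exon_label: str,
                                         deleted_prefix_nt: int,
                                         domain_map: pd.DataFrame | None = None,
                                         ) -> SpliceOutcome:
    """Protein consequence of a cryptic acceptor site within an exon,
    which removes the first ``deleted_prefix_nt`` bases of that exon."""
    start, end = model.exon_span(exon_label)
    if not 0 < deleted_prefix_nt < end - start:
        raise ValidationError(
            f"deleted prefix must be within (0, {end - start}) nt for exon "
            f"{exon_label}, got {deleted_prefix_nt}")
    return _consequence(model, (start, start + deleted_prefix_nt), domain_map)


def load_domain_map(path: str | Path) -> pd.DataFrame:
    """Read a protein-domain map TSV with columns domain, aa_start, aa_end."""
    df = pd.read_csv(path, sep="\t")
    if missing := {"domain", "aa_start", "aa_end"} - set(df.columns):
        raise ValidationError(f"domain map missing columns: {sorted(missing)}")
    return df


def _data_path(name: str):
    return resources.files("aequovar.data").joinpath(name)


def synthetic_cnga1_model() -> TranscriptModel:
    """Packaged synthetic stand-in for the MANE Select *CNGA1* transcript.

    Exon labels and the frame-relevant features match the published
    structure (11 exons, CDS from exon 4 to exon 11, 686-aa protein,
    108-nt coding exon 9); individual exon lengths are synthetic.
    """
    with resources.as_file(_data_path("synthetic_cnga1_transcript.tsv")) as p:
        return TranscriptModel.from_exon_table(p, transcript_id="SYNTH_CNGA1_MANE")


def synthetic_cnga1_domains() -> pd.DataFrame:
    """Packaged synthetic CNGA1 protein-domain map (686-aa numbering)."""
    with resources.as_file(_data_path("synthetic_cnga1_domains.tsv")) as p:
        return load_domain_map(p)
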
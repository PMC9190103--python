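"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions (the single conversion point for the package):
internal coordinates are 0-based half-open everywhere; GFF3 output is
1-based inclusive; BED/bedGraph stay 0-based half-open. SAM input is parsed
with pysam (POS 1-based in the file, 0-based from the API).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import gffutils
import numpy as np
import pysam
from Bio import SeqIO

from .core import GenomeSequence, GenomicInterval, ReadAlignment
from .struct_annot import IntactLTRRT

logger = logging.getLogger(__name__)

_AMBIGUOUS = re.compile(r"[RYSWKMBDHV]")

#: MAPQ at and above which an alignment counts as uniquely mapped, when the
#: aligner reports an informative MAPQ (255 means "unavailable").
DEFAULT_MAPQ_UNIQUE = 10


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Lowercase is normalized to uppercase; IUPAC ambiguity codes other than N
    collapse to N (with a logged warning) so public genomes parse.
    """
    records: Dict[str, str] = {}
    warned = False
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate id {rec.id}")
        seq = str(rec.seq).upper()
        cleaned = _AMBIGUOUS.sub("N", seq)
        if cleaned != seq and not warned:
            logger.warning(
                "%s: IUPAC ambiguity codes collapsed to N (first in %s)",
                path, rec.id,
            )
            warned = True
        records[rec.id] = cleaned
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


@dataclass
class AnnotatedElement:
    """An element as written to / read back from the package's GFF3.

    ``ltr_left``/``ltr_right`` are in genomic order; for a '-' strand element
    the biological 5' LTR is ``ltr_right``.
    """

    element_id: str
    interval: GenomicInterval
    ltr_left: GenomicInterval
    ltr_right: GenomicInterval
    pbs_interval: Optional[GenomicInterval] = None
    ppt_interval: Optional[GenomicInterval] = None
    tsd_left: Optional[GenomicInterval] = None
    tsd_right: Optional[GenomicInterval] = None
    domains: List[Tuple[str, GenomicInterval, int, float]] = field(default_factory=list)
    family: str = "unknown"
    superfamily: str = "unknown"
    k: Optional[float] = None
    age_years: Optional[float] = None
    ltr_similarity: Optional[float] = None

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def five_ltr_bio(self) -> GenomicInterval:
        """The biological 5' LTR (strand-aware)."""
        return self.ltr_right if self.strand == "-" else self.ltr_left


def annotated_from_intact(el: IntactLTRRT) -> AnnotatedElement:
    c = el.candidate
    e = el.interval
    tsd_len = len(el.tsd.left_flank)
    return AnnotatedElement(
        element_id=el.element_id or "unnamed",
        interval=e,
        ltr_left=c.five_ltr,
        ltr_right=c.three_ltr,
        pbs_interval=el.pbs.interval,
        ppt_interval=el.ppt.interval,
        tsd_left=GenomicInterval(e.seq_id, e.start - tsd_len, e.start),
        tsd_right=GenomicInterval(e.seq_id, e.end, e.end + tsd_len),
        domains=[(d.name, d.interval, d.frame, d.identity) for d in el.domains],
        family=el.family,
        superfamily=el.superfamily,
        k=el.kimura.k if el.kimura else None,
        age_years=el.age.T if el.age else None,
        ltr_similarity=c.ltr_similarity,
    )


def _gff_line(
    seq_id: str, ftype: str, iv: GenomicInterval, strand: str, attrs: str
) -> str:
    # 0-based half-open -> 1-based inclusive
    return f"{seq_id}\tltrscout\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\t{attrs}"


def write_gff3(elements: Sequence, path) -> None:
    """Write elements (IntactLTRRT or AnnotatedElement) as GFF3.

    One ``LTR_retrotransposon`` parent per element with child features for
    each LTR, PBS, PPT, TSD and protein domain. TSD children flank the parent
    interval (the duplication lies outside the element by definition).
    """
    anns = [
        annotated_from_intact(e) if isinstance(e, IntactLTRRT) else e
        for e in elements
    ]
    lines = ["##gff-version 3"]
    for a in anns:
        strand = a.strand if a.strand in "+-" else "."
        eid = a.element_id
        attrs = [f"ID={eid}", f"family={a.family}", f"superfamily={a.superfamily}"]
        if a.ltr_similarity is not None:
            attrs.append(f"ltr_similarity={a.ltr_similarity:.6g}")
        if a.k is not None:
            attrs.append(f"k={a.k:.10g}")
        if a.age_years is not None:
            attrs.append(f"age_years={a.age_years:.10g}")
        lines.append(
            _gff_line(a.interval.seq_id, "LTR_retrotransposon", a.interval, strand,
                      ";".join(attrs))
        )
        for label, iv in (("ltr1", a.ltr_left), ("ltr2", a.ltr_right)):
            lines.append(
                _gff_line(a.interval.seq_id, "long_terminal_repeat", iv, strand,
                          f"ID={eid}_{label};Parent={eid}")
            )
        if a.pbs_interval is not None:
            lines.append(
                _gff_line(a.interval.seq_id, "primer_binding_site", a.pbs_interval,
                          strand, f"ID={eid}_pbs;Parent={eid}")
            )
        if a.ppt_interval is not None:
            lines.append(
                _gff_line(a.interval.seq_id, "RR_tract", a.ppt_interval, strand,
                          f"ID={eid}_ppt;Parent={eid}")
            )
        for label, iv in (("tsd1", a.tsd_left), ("tsd2", a.tsd_right)):
            if iv is not None:
                lines.append(
                    _gff_line(a.interval.seq_id, "target_site_duplication", iv,
                              strand, f"ID={eid}_{label};Parent={eid}")
                )
        for n, (name, iv, frame, ident) in enumerate(a.domains):
            lines.append(
                _gff_line(
                    a.interval.seq_id, "protein_match", iv, strand,
                    f"ID={eid}_dom{n};Parent={eid};Name={name};"
                    f"frame={frame:+d};identity={ident:.6g}",
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> List[AnnotatedElement]:
    """Read a GFF3 written by :func:`write_gff3` back into records.

    Round-trips coordinates, strands and the attributes this package writes.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: List[AnnotatedElement] = []
    for feat in db.features_of_type("LTR_retrotransposon", order_by="start"):
        eid = feat.id
        strand = feat.strand if feat.strand in "+-" else "."
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
        ltrs: List[GenomicInterval] = []
        ann = AnnotatedElement(
            element_id=eid,
            interval=iv,
            ltr_left=iv,  # placeholders until children are read
            ltr_right=iv,
            family=feat.attributes.get("family", ["unknown"])[0],
            superfamily=feat.attributes.get("superfamily", ["unknown"])[0],
        )
        for key, attr in (("k", "k"), ("age_years", "age_years"),
                          ("ltr_similarity", "ltr_similarity")):
            if attr in feat.attributes:
                setattr(ann, key, float(feat.attributes[attr][0]))
        for child in db.children(eid, order_by="start"):
            civ = GenomicInterval(child.seqid, child.start - 1, child.end, strand)
            if child.featuretype == "long_terminal_repeat":
                ltrs.append(civ)
            elif child.featuretype == "primer_binding_site":
                ann.pbs_interval = civ
            elif child.featuretype == "RR_tract":
                ann.ppt_interval = civ
            elif child.featuretype == "target_site_duplication":
                if civ.end <= iv.start:
                    ann.tsd_left = civ
                else:
                    ann.tsd_right = civ
            elif child.featuretype == "protein_match":
                ann.domains.append(
                    (
                        child.attributes["Name"][0],
                        civ,
                        int(child.attributes["frame"][0]),
                        float(child.attributes["identity"][0]),
                    )
                )
        if len(ltrs) != 2:
            raise ValueError(f"element {eid} lacks two LTR children")
        ltrs.sort(key=lambda x: x.start)
        ann.ltr_left, ann.ltr_right = ltrs
        out.append(ann)
    return out


# ---------------------------------------------------------------------------
# SAM


def sam_references(path) -> Tuple[str, ...]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return tuple(fh.references)


def _check_rnames(path) -> None:
    """Reject records whose RNAME is absent from the header (pysam would
    silently demote them to unmapped)."""
    refs = set(sam_references(path))
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.split("\t", 4)
            if len(fields) > 3 and fields[2] not in ("*", "") \
                    and fields[2] not in refs:
                raise ValueError(
                    f"invalid SAM {path}: RNAME {fields[2]!r} absent from header"
                )


def read_alignments(path, mapq_unique: int = DEFAULT_MAPQ_UNIQUE) -> List[ReadAlignment]:
    """Parse a SAM file into :class:`ReadAlignment` records.

    Unmapped and secondary/supplementary records are skipped. A record is
    uniquely mapped when MAPQ >= ``mapq_unique`` if MAPQ is informative
    (!= 255), else when the secondary flag is absent. Mate intervals are
    resolved by read id after the pass.
    """
    records: List[Tuple[str, GenomicInterval, bool]] = []
    _check_rnames(path)
    try:
        with pysam.AlignmentFile(str(path), "r") as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.reference_name is None or rec.reference_end is None:
                    continue
                iv = GenomicInterval(
                    rec.reference_name, rec.reference_start, rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
                if rec.mapping_quality != 255:
                    unique = rec.mapping_quality >= mapq_unique
                else:
                    unique = not rec.is_secondary
                records.append((rec.query_name, iv, unique))
    except ValueError as err:
        raise ValueError(f"invalid SAM {path}: {err}") from err
    by_name: Dict[str, List[int]] = {}
    for n, (qname, _, _) in enumerate(records):
        by_name.setdefault(qname, []).append(n)
    out: List[ReadAlignment] = []
    for qname, iv, unique in records:
        idxs = by_name[qname]
        mate = None
        if len(idxs) == 2:
            other = records[idxs[0]] if records[idxs[1]][1] == iv else records[idxs[1]]
            if other[1] != iv:
                mate = other[1]
        out.append(ReadAlignment(read_id=qname, interval=iv,
                                 mate_interval=mate, is_unique=unique))
    return out


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(coverage, seq_id: str, path) -> None:
    """Run-length-encode a per-base coverage vector as bedGraph
    (0-based half-open); zero runs are omitted."""
    cov = np.asarray(coverage)
    if cov.size and cov.min() < 0:
        raise ValueError("negative coverage")
    with open(path, "w") as fh:
        _write_bedgraph_body(cov, seq_id, fh)


def _write_bedgraph_body(cov: np.ndarray, seq_id: str, fh) -> None:
    if cov.size == 0:
        return
    change = np.flatnonzero(np.diff(cov)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [cov.size]])
    for s, e in zip(starts, ends):
        v = cov[s]
        if v != 0:
            fh.write(f"{seq_id}\t{s}\t{e}\t{v:g}\n")


def write_bedgraph_multi(coverages: Dict[str, np.ndarray], path) -> None:
    """bedGraph for several sequences in one file (sorted by sequence id)."""
    with open(path, "w") as fh:
        for seq_id in sorted(coverages):
            _write_bedgraph_body(np.asarray(coverages[seq_id]), seq_id, fh)
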
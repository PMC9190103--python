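"""End-to-end workflows chaining the pipeline stages.

Two workflows mirror the analysis: (1) genome annotation — detect LTR
pairs, apply the structural intactness filter, classify, and date; and
(2) ALE-seq calling — count reads over the annotation, normalize, measure
the junction signature, and tier activity.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import age as age_mod
from . import aleseq, io, ltr_detect, struct_annot
from .config import RunConfig
from .core import GenomeSequence, ReadAlignment
from .io import AnnotatedElement
from .struct_annot import IntactLTRRT, Rejection

logger = logging.getLogger(__name__)


def superfamily_shares(counts: Dict[str, int]) -> Dict[str, float]:
    """Percentage share per superfamily from a census of element counts."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty census")
    return {name: 100.0 * n / total for name, n in counts.items()}


@dataclass
class AnnotationResult:
    elements: List[IntactLTRRT]
    rejections: List[Rejection]
    candidates: List[ltr_detect.LTRCandidate]

    def summary(self) -> str:
        sf = Counter(e.superfamily for e in self.elements)
        fam = Counter(e.family for e in self.elements)
        total = len(self.elements)
        parts = [f"{total} intact LTR-RTs"]
        for name in sorted(sf):
            share = 100.0 * sf[name] / total if total else 0.0
            parts.append(f"{sf[name]} {name}-type ({share:.1f}%)")
        fam_str = ", ".join(f"{f}:{n}" for f, n in sorted(fam.items()))
        return "; ".join(parts) + (f" | families {fam_str}" if fam_str else "")


def annotate_genome(
    genome: GenomeSequence,
    trnas: GenomeSequence,
    config: Optional[RunConfig] = None,
) -> AnnotationResult:
    """Detect, filter, classify and date intact LTR retrotransposons."""
    config = config or RunConfig()
    candidates = ltr_detect.find_ltr_pairs(genome, config.detection_params())
    logger.info("detected %d candidate LTR pairs", len(candidates))
    ann_params = config.annotation_params()
    elements: List[IntactLTRRT] = []
    rejections: List[Rejection] = []
    for cand in candidates:
        result = struct_annot.annotate_candidate(genome, cand, trnas, ann_params)
        if isinstance(result, IntactLTRRT):
            elements.append(result)
        else:
            rejections.append(result)
    for n, el in enumerate(elements):
        el.element_id = f"LTRRT_{n + 1:04d}"
        kim, age_est, saturated = age_mod.date_element(
            genome, el, r=config.substitution_rate
        )
        el.kimura, el.age, el.saturated = kim, age_est, saturated
    logger.info(
        "accepted %d intact elements, rejected %d candidates",
        len(elements), len(rejections),
    )
    return AnnotationResult(elements=elements, rejections=rejections,
                            candidates=candidates)


def rejections_table(rejections: Sequence[Rejection]) -> pd.DataFrame:
    rows = []
    for n, r in enumerate(rejections):
        e = r.candidate.element
        rows.append(
            {
                "candidate_id": f"cand_{n + 1:04d}",
                "seq_id": e.seq_id,
                "start": e.start,
                "end": e.end,
                "reason_codes": ",".join(sorted(r.reason_codes)),
            }
        )
    return pd.DataFrame(
        rows, columns=["candidate_id", "seq_id", "start", "end", "reason_codes"]
    )


def ages_table(elements: Sequence[IntactLTRRT]) -> pd.DataFrame:
    """Per-element dating table: P, Q, k, compared sites, T (years)."""
    rows = []
    for el in elements:
        row = {
            "element_id": el.element_id,
            "seq_id": el.interval.seq_id,
            "start": el.interval.start,
            "end": el.interval.end,
            "family": el.family,
            "superfamily": el.superfamily,
        }
        if el.kimura is not None:
            row.update(
                P=el.kimura.P, Q=el.kimura.Q, k=el.kimura.k,
                compared_sites=el.kimura.compared_sites, T_years=el.age.T,
            )
        else:
            row.update(P=float("nan"), Q=float("nan"), k=float("nan"),
                       compared_sites=0, T_years=float("nan"))
        row["saturated"] = el.saturated
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["element_id", "seq_id", "start", "end", "family", "superfamily",
                 "P", "Q", "k", "compared_sites", "T_years", "saturated"],
    )


def rt_proteins(elements: Sequence[IntactLTRRT]) -> Dict[str, str]:
    """RT-domain protein per element (input to the phylogeny stage)."""
    return {el.element_id: el.rt_hit.protein for el in elements}


def aleseq_stats(
    alignments: Sequence[ReadAlignment],
    elements: Sequence[AnnotatedElement],
    config: Optional[RunConfig] = None,
    references: Optional[Sequence[str]] = None,
) -> List[aleseq.ElementReadStats]:
    config = config or RunConfig()
    return aleseq.compute_element_stats(
        alignments,
        elements,
        strong_rpm=config.strong_rpm,
        moderate_rpm=config.moderate_rpm,
        min_junction=config.min_junction,
        window_up=config.junction_window_up,
        window_down=config.junction_window_down,
        references=references,
    )


def stats_table(
    stats: Sequence[aleseq.ElementReadStats],
    elements: Sequence[AnnotatedElement],
) -> pd.DataFrame:
    pos = {e.element_id: e.interval for e in elements}
    rows = []
    for s in stats:
        iv = pos[s.element_id]
        rows.append(
            {
                "element_id": s.element_id,
                "seq_id": iv.seq_id,
                "start": iv.start,
                "end": iv.end,
                "raw_count": s.raw_count,
                "normalized_rpm": s.normalized,
                "junction_reads": s.junction_reads,
                "call": s.call,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["element_id", "seq_id", "start", "end", "raw_count",
                 "normalized_rpm", "junction_reads", "call"],
    )


def manhattan_plot(
    stats: Sequence[aleseq.ElementReadStats],
    elements: Sequence[AnnotatedElement],
    chrom_lengths: Dict[str, int],
    path,
) -> None:
    """Element genomic position vs normalized RPM, colored by activity tier."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    offsets: Dict[str, int] = {}
    total = 0
    for name in chrom_lengths:
        offsets[name] = total
        total += chrom_lengths[name]
    pos = {e.element_id: e.interval for e in elements}
    colors = {"strong": "tab:green", "moderate": "tab:blue", "none": "0.3"}
    fig, ax = plt.subplots(figsize=(9, 3.2))
    for tier in ("none", "moderate", "strong"):
        xs = [
            offsets[pos[s.element_id].seq_id]
            + (pos[s.element_id].start + pos[s.element_id].end) / 2
            for s in stats if s.call == tier
        ]
        ys = [s.normalized for s in stats if s.call == tier]
        if xs:
            ax.scatter(xs, ys, s=18, c=colors[tier], label=tier, zorder=3)
    for name, off in offsets.items():
        ax.axvline(off, color="0.85", lw=0.8, zorder=1)
        ax.text(off + chrom_lengths[name] / 2, ax.get_ylim()[1] * 0.98, name,
                ha="center", va="top", fontsize=8, color="0.4")
    ax.set_xlabel("genomic position")
    ax.set_ylabel("normalized reads (RPM)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
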
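"""Synthetic genomes and ALE-seq reads with a complete ground truth.

The generator implants structurally intact LTR retrotransposons — 5-bp TSD,
``TG...CA`` LTRs, a PBS complementary to a bundled tRNA 3' end, a coding
cassette back-translated from family exemplar proteins, a polypurine tract,
and a 3' LTR derived from the 5' LTR under the Kimura two-parameter process
at a target divergence — plus decoy insertions (solo LTRs, 3'-truncated
copies, TSD-less copies) into random background sequence. Designated
"active" elements then emit paired 30-bp read fragments spanning the
5' LTR - PBS junction (the eclDNA signature that ALE-seq libraries capture),
on top of uniform background fragments.

Everything is driven by a single mandatory seed: identical configuration and
seed give byte-identical FASTA/FASTQ/SAM/truth output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pysam
from Bio.Data import CodonTable

from . import refs
from .core import (
    Fragment,
    GenomeSequence,
    GenomicInterval,
    ReadAlignment,
    reverse_complement,
)
from .io import AnnotatedElement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}

#: transition partner (A<->G, C<->T) under the encoding A=0 C=1 G=2 T=3
_TRANSITION = np.array([2, 3, 0, 1])
#: the two transversion partners per base
_TRANSVERSION = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])

_TSD_LEN = 5
_PBS_LEN = 12
_PPT_LEN = 12


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated experiment.

    Defaults are the package's calibration scenario: a 2-Mb two-chromosome
    genome carrying 50 intact elements of mixed family, two of which are
    active with 500 junction fragments each over 100,000 background
    fragments of 30-bp paired-end reads (template cap 3,000 bp).
    """

    seed: int
    chrom_lengths: Tuple[Tuple[str, int], ...] = (
        ("chr1", 1_000_000),
        ("chr2", 1_000_000),
    )
    n_intact: int = 50
    n_solo_ltr: int = 0
    n_truncated: int = 0
    n_no_tsd: int = 0
    family_mix: Tuple[str, ...] = refs.ALL_FAMILIES
    ltr_len_range: Tuple[int, int] = (300, 1000)
    divergence_levels: Tuple[float, ...] = (0.0, 0.005, 0.01, 0.02)
    kappa: float = 2.0
    active_ids: Optional[Tuple[str, ...]] = None
    n_active: int = 2
    n_junction_fragments: int = 500
    n_background_fragments: int = 100_000
    read_len: int = 30
    max_template: int = 3000
    gc_content: float = 0.5

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, n in (
            ("n_intact", self.n_intact),
            ("n_solo_ltr", self.n_solo_ltr),
            ("n_truncated", self.n_truncated),
            ("n_no_tsd", self.n_no_tsd),
            ("n_junction_fragments", self.n_junction_fragments),
            ("n_background_fragments", self.n_background_fragments),
        ):
            if n < 0:
                raise ValueError(f"{name} must be >= 0")
        for k in self.divergence_levels:
            _k2p_site_probs(k, self.kappa)  # raises beyond saturation
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        if self.ltr_len_range[0] > self.ltr_len_range[1]:
            raise ValueError("invalid ltr_len_range")
        unknown = set(self.family_mix) - set(refs.ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown families {sorted(unknown)}")


@dataclass
class TruthElement:
    """Ground truth for one implanted element (or decoy)."""

    element_id: str
    decoy_class: Optional[str]  # None | solo_ltr | truncated | no_tsd
    interval: GenomicInterval  # element span, TSD-exclusive
    ltr5: Optional[GenomicInterval] = None
    ltr3: Optional[GenomicInterval] = None
    pbs: Optional[GenomicInterval] = None
    ppt: Optional[GenomicInterval] = None
    domains: List[Tuple[str, GenomicInterval]] = field(default_factory=list)
    family: Optional[str] = None
    superfamily: Optional[str] = None
    k: Optional[float] = None
    trna_id: Optional[str] = None
    tsd: Optional[str] = None
    active: bool = False

    @property
    def is_intact(self) -> bool:
        return self.decoy_class is None


@dataclass
class TruthSet:
    """Serializable oracle: implanted structures plus per-fragment sources."""

    elements: List[TruthElement] = field(default_factory=list)
    fragment_sources: Dict[str, str] = field(default_factory=dict)

    def intact(self) -> List[TruthElement]:
        return [e for e in self.elements if e.is_intact]

    def decoys(self) -> List[TruthElement]:
        return [e for e in self.elements if not e.is_intact]

    def by_id(self, element_id: str) -> TruthElement:
        for e in self.elements:
            if e.element_id == element_id:
                return e
        raise KeyError(element_id)

    # -- lossless JSON round-trip -------------------------------------------

    def to_json(self) -> str:
        def iv(x):
            return None if x is None else [x.seq_id, x.start, x.end, x.strand]

        payload = {
            "elements": [
                {
                    "element_id": e.element_id,
                    "decoy_class": e.decoy_class,
                    "interval": iv(e.interval),
                    "ltr5": iv(e.ltr5),
                    "ltr3": iv(e.ltr3),
                    "pbs": iv(e.pbs),
                    "ppt": iv(e.ppt),
                    "domains": [[n, iv(d)] for n, d in e.domains],
                    "family": e.family,
                    "superfamily": e.superfamily,
                    "k": e.k,
                    "trna_id": e.trna_id,
                    "tsd": e.tsd,
                    "active": e.active,
                }
                for e in self.elements
            ],
            "fragment_sources": self.fragment_sources,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        def iv(x):
            return None if x is None else GenomicInterval(*x)

        data = json.loads(text)
        elements = [
            TruthElement(
                element_id=d["element_id"],
                decoy_class=d["decoy_class"],
                interval=iv(d["interval"]),
                ltr5=iv(d["ltr5"]),
                ltr3=iv(d["ltr3"]),
                pbs=iv(d["pbs"]),
                ppt=iv(d["ppt"]),
                domains=[(n, iv(x)) for n, x in d["domains"]],
                family=d["family"],
                superfamily=d["superfamily"],
                k=d["k"],
                trna_id=d["trna_id"],
                tsd=d["tsd"],
                active=d["active"],
            )
            for d in data["elements"]
        ]
        return cls(elements=elements, fragment_sources=dict(data["fragment_sources"]))


def truth_to_annotated(truth: TruthSet) -> List[AnnotatedElement]:
    """Truth intact elements as annotation records (the 'customized
    annotation file' of the read-counting stage)."""
    out = []
    for e in truth.intact():
        out.append(
            AnnotatedElement(
                element_id=e.element_id,
                interval=e.interval,
                ltr_left=e.ltr5,
                ltr_right=e.ltr3,
                pbs_interval=e.pbs,
                ppt_interval=e.ppt,
                domains=[(n, d, 1, 1.0) for n, d in e.domains],
                family=e.family or "unknown",
                superfamily=e.superfamily or "unknown",
                k=e.k,
            )
        )
    return out


# ---------------------------------------------------------------------------
# K2P mutation process


def _k2p_site_probs(target_k: float, kappa: float) -> Tuple[float, float]:
    """Per-site transition / total transversion probabilities after evolving
    for K2P distance ``target_k`` at rate ratio ``kappa`` (alpha/beta)."""
    if target_k < 0:
        raise ValueError("target_k must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * beta * target_k) \
        - 0.5 * math.exp(-2.0 * (alpha + beta) * target_k)
    p_tv = 0.5 - 0.5 * math.exp(-4.0 * beta * target_k)
    if 1.0 - 2.0 * p_ts - p_tv <= 0 or 1.0 - 2.0 * p_tv <= 0:
        raise ValueError(f"target_k={target_k} beyond saturation for kappa={kappa}")
    return p_ts, p_tv


def mutate_k2p(
    seq: str, target_k: float, kappa: float, rng: np.random.Generator
) -> str:
    """Evolve ``seq`` under the K2P substitution process to distance
    ``target_k`` (expected substitutions/site), transition:transversion rate
    ratio ``kappa``. The estimator in :func:`ltrscout.age.kimura2p` is the
    exact inverse of this process in expectation."""
    p_ts, p_tv = _k2p_site_probs(target_k, kappa)
    codes = np.array([_CODE.get(c, -1) for c in seq])
    n = codes.size
    u = rng.random(n)
    tv_choice = rng.integers(0, 2, n)
    out = codes.copy()
    valid = codes >= 0
    ts_mask = valid & (u < p_ts)
    tv_mask = valid & (u >= p_ts) & (u < p_ts + p_tv)
    out[ts_mask] = _TRANSITION[codes[ts_mask]]
    out[tv_mask] = _TRANSVERSION[codes[tv_mask], tv_choice[tv_mask]]
    chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    chars[valid] = _BASES[out[valid]]
    return chars.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# sequence construction helpers


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=n, p=p)
    return _BASES[draws].tobytes().decode("ascii")


def _codon_map() -> Dict[str, List[str]]:
    fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
    out: Dict[str, List[str]] = {}
    for codon, aa in fwd.items():
        out.setdefault(aa, []).append(codon)
    return {aa: sorted(cods) for aa, cods in out.items()}


_AA_CODONS = _codon_map()


def backtranslate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice per residue, from seeded randomness."""
    parts = []
    for aa in protein:
        codons = _AA_CODONS[aa]
        parts.append(codons[rng.integers(0, len(codons))])
    return "".join(parts)


def _make_ltr(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "TG" + _random_dna(rng, length - 4) + "CA"


def _mismatched_flank(flank: str, rng: np.random.Generator) -> str:
    """A flank differing from ``flank`` at every position (TSD homology 0)."""
    out = []
    for c in flank:
        others = [b for b in "ACGT" if b != c]
        out.append(others[rng.integers(0, 3)])
    return "".join(out)


# ---------------------------------------------------------------------------
# genome construction


@dataclass
class _Block:
    """A constructed insert: flanks + body, with body-relative features."""

    seq: str
    body_start: int  # offset of the element (TSD-exclusive) within seq
    body_len: int
    features: Dict[str, Tuple[int, int]]
    domains: List[Tuple[str, Tuple[int, int]]]
    family: Optional[str]
    superfamily: Optional[str]
    k: Optional[float]
    trna_id: Optional[str]
    tsd: Optional[str]
    decoy_class: Optional[str]


def _build_intact_body(
    rng: np.random.Generator,
    config: SimulationConfig,
    family: str,
    target_k: float,
    trna_id: str,
    trna_seq: str,
) -> Tuple[str, Dict[str, Tuple[int, int]], List[Tuple[str, Tuple[int, int]]]]:
    lo, hi = config.ltr_len_range
    ltr5 = _make_ltr(rng, lo, hi)
    off_len = int(rng.integers(0, 7))
    off = _random_dna(rng, off_len) if off_len else ""
    pbs = reverse_complement(trna_seq[-_PBS_LEN:])
    spacer1 = _random_dna(rng, int(rng.integers(40, 81)))
    cassette_parts = []
    dom_rel: List[Tuple[str, Tuple[int, int]]] = []
    pos = 0
    for name, protein in refs.superfamily_cassette(family):
        cds = backtranslate(protein, rng)
        dom_rel.append((name, (pos, pos + len(cds))))
        cassette_parts.append(cds)
        pos += len(cds)
    cassette = "".join(cassette_parts)
    spacer2 = _random_dna(rng, int(rng.integers(40, 81)))
    ppt = "".join("AG"[rng.integers(0, 2)] for _ in range(_PPT_LEN))
    gap = _random_dna(rng, int(rng.integers(0, 13)))
    ltr3 = mutate_k2p(ltr5, target_k, config.kappa, rng)
    parts = [ltr5, off, pbs, spacer1, cassette, spacer2, ppt, gap, ltr3]
    offsets = np.cumsum([0] + [len(p) for p in parts])
    body = "".join(parts)
    features = {
        "ltr5": (0, len(ltr5)),
        "pbs": (int(offsets[2]), int(offsets[3])),
        "ppt": (int(offsets[6]), int(offsets[7])),
        "ltr3": (int(offsets[8]), int(offsets[9])),
    }
    cassette_start = int(offsets[4])
    domains = [(n, (cassette_start + s, cassette_start + e)) for n, (s, e) in dom_rel]
    return body, features, domains


def _build_block(
    rng: np.random.Generator,
    config: SimulationConfig,
    decoy_class: Optional[str],
    family: str,
    target_k: float,
    trna_id: str,
    trna_seq: str,
) -> _Block:
    tsd = _random_dna(rng, _TSD_LEN)
    if decoy_class == "solo_ltr":
        body = _make_ltr(rng, *config.ltr_len_range)
        return _Block(
            seq=tsd + body + tsd, body_start=_TSD_LEN, body_len=len(body),
            features={"ltr5": (0, len(body))}, domains=[], family=None,
            superfamily=None, k=None, trna_id=None, tsd=tsd,
            decoy_class=decoy_class,
        )
    body, features, domains = _build_intact_body(
        rng, config, family, target_k, trna_id, trna_seq
    )
    if decoy_class == "truncated":
        # lose the 3' LTR and everything from the PPT on
        cut = features["ppt"][0]
        body = body[:cut]
        features = {k: v for k, v in features.items() if v[1] <= cut}
        domains = [(n, iv) for n, iv in domains if iv[1] <= cut]
        right = _random_dna(rng, _TSD_LEN)
        return _Block(
            seq=tsd + body + right, body_start=_TSD_LEN, body_len=len(body),
            features=features, domains=domains, family=family,
            superfamily=refs.superfamily_of(family), k=None, trna_id=trna_id,
            tsd=None, decoy_class=decoy_class,
        )
    if decoy_class == "no_tsd":
        right = _mismatched_flank(tsd, rng)
        return _Block(
            seq=tsd + body + right, body_start=_TSD_LEN, body_len=len(body),
            features=features, domains=domains, family=family,
            superfamily=refs.superfamily_of(family), k=target_k,
            trna_id=trna_id, tsd=None, decoy_class=decoy_class,
        )
    return _Block(
        seq=tsd + body + tsd, body_start=_TSD_LEN, body_len=len(body),
        features=features, domains=domains, family=family,
        superfamily=refs.superfamily_of(family), k=target_k, trna_id=trna_id,
        tsd=tsd, decoy_class=None,
    )


_PLACEMENT_MARGIN = 50
_MAX_PLACEMENT_TRIES = 2000


def build_genome(config: SimulationConfig) -> Tuple[GenomeSequence, TruthSet]:
    """Emit a genome with implanted elements/decoys and its ground truth."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    trnas = refs.trna_set()
    trna_ids = sorted(trnas)

    chrom_names = [n for n, _ in config.chrom_lengths]
    chrom_arrays: Dict[str, np.ndarray] = {}
    for name, length in config.chrom_lengths:
        seq = _random_dna(rng, length, config.gc_content)
        chrom_arrays[name] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    occupied: Dict[str, List[Tuple[int, int]]] = {n: [] for n in chrom_names}
    lengths = np.array([l for _, l in config.chrom_lengths], dtype=float)
    chrom_p = lengths / lengths.sum()

    plan: List[Optional[str]] = [None] * config.n_intact
    plan += ["solo_ltr"] * config.n_solo_ltr
    plan += ["truncated"] * config.n_truncated
    plan += ["no_tsd"] * config.n_no_tsd

    truth = TruthSet()
    for idx, decoy_class in enumerate(plan):
        family = config.family_mix[idx % len(config.family_mix)]
        target_k = config.divergence_levels[idx % len(config.divergence_levels)]
        trna_id = trna_ids[idx % len(trna_ids)]
        block = _build_block(
            rng, config, decoy_class, family, target_k, trna_id, trnas[trna_id]
        )
        placed = _place_block(rng, chrom_arrays, occupied, chrom_names, chrom_p, block)
        if placed is None:
            raise ValueError(
                f"genome too small to place insert {idx} "
                f"({len(block.seq)} bp): increase chromosome lengths"
            )
        chrom, start = placed
        body0 = start + block.body_start
        element_id = f"elem_{idx + 1:04d}"

        def g(rel: Tuple[int, int]) -> GenomicInterval:
            return GenomicInterval(chrom, body0 + rel[0], body0 + rel[1], "+")

        truth.elements.append(
            TruthElement(
                element_id=element_id,
                decoy_class=block.decoy_class,
                interval=GenomicInterval(chrom, body0, body0 + block.body_len, "+"),
                ltr5=g(block.features["ltr5"]) if "ltr5" in block.features else None,
                ltr3=g(block.features["ltr3"]) if "ltr3" in block.features else None,
                pbs=g(block.features["pbs"]) if "pbs" in block.features else None,
                ppt=g(block.features["ppt"]) if "ppt" in block.features else None,
                domains=[(n, g(iv)) for n, iv in block.domains],
                family=block.family,
                superfamily=block.superfamily,
                k=block.k,
                trna_id=block.trna_id,
                tsd=block.tsd,
            )
        )

    _mark_active(config, truth)
    records = {n: chrom_arrays[n].tobytes().decode("ascii") for n in chrom_names}
    return GenomeSequence(records), truth


def _place_block(rng, chrom_arrays, occupied, chrom_names, chrom_p, block):
    n = len(block.seq)
    for _ in range(_MAX_PLACEMENT_TRIES):
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
        arr = chrom_arrays[chrom]
        if len(arr) <= n + 2 * _PLACEMENT_MARGIN:
            continue
        start = int(rng.integers(_PLACEMENT_MARGIN, len(arr) - n - _PLACEMENT_MARGIN))
        window = (start - _PLACEMENT_MARGIN, start + n + _PLACEMENT_MARGIN)
        if any(window[0] < e and s < window[1] for s, e in occupied[chrom]):
            continue
        arr[start : start + n] = np.frombuffer(block.seq.encode("ascii"), dtype=np.uint8)
        occupied[chrom].append((start, start + n))
        return chrom, start
    return None


def _mark_active(config: SimulationConfig, truth: TruthSet) -> None:
    intact_ids = [e.element_id for e in truth.intact()]
    if config.active_ids is not None:
        unknown = set(config.active_ids) - set(intact_ids)
        if unknown:
            raise ValueError(f"active_ids not among intact elements: {sorted(unknown)}")
        chosen = set(config.active_ids)
    else:
        chosen = set(intact_ids[: config.n_active])
    for e in truth.elements:
        e.active = e.element_id in chosen


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimulatedReads:
    """In-memory truth alignments plus SAM/FASTQ writers."""

    genome: GenomeSequence
    alignments: List[ReadAlignment]
    fragments: List[Fragment]
    read_len: int

    def write_sam(self, path) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": n, "LN": l} for n, l in self.genome.lengths().items()
            ],
        }
        qual = "I" * self.read_len
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            tid = {n: i for i, n in enumerate(self.genome.lengths())}
            for aln in self.alignments:
                rec = pysam.AlignedSegment()
                rec.query_name = aln.read_id
                iv = aln.interval
                rec.reference_id = tid[iv.seq_id]
                rec.reference_start = iv.start
                rec.mapping_quality = 42 if aln.is_unique else 3
                rec.cigarstring = f"{iv.length}M"
                first = aln.mate_interval is None or iv.start <= aln.mate_interval.start
                flag = 1 | 2  # paired, proper
                if iv.strand == "-":
                    flag |= 16
                if aln.mate_interval is not None:
                    mate = aln.mate_interval
                    flag |= 64 if iv.strand == "+" else 128
                    if mate.strand == "-":
                        flag |= 32
                    rec.next_reference_id = tid[mate.seq_id]
                    rec.next_reference_start = mate.start
                    span = max(iv.end, mate.end) - min(iv.start, mate.start)
                    rec.template_length = span if first else -span
                rec.flag = flag
                # SAM stores SEQ on the forward reference strand
                rec.query_sequence = self.genome.fetch(
                    GenomicInterval(iv.seq_id, iv.start, iv.end)
                )
                rec.query_qualities = pysam.qualitystring_to_array(qual)
                out.write(rec)

    def write_fastq(self, r1_path, r2_path) -> None:
        qual = "I" * self.read_len
        pairs: Dict[str, Dict[str, str]] = {}
        for aln in self.alignments:
            seq = self.genome.fetch(aln.interval)
            if aln.interval.strand == "-":
                seq = reverse_complement(seq)
            mate = "r1" if aln.interval.strand == "+" else "r2"
            pairs.setdefault(aln.read_id, {})[mate] = seq
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for rid in sorted(pairs):
                p = pairs[rid]
                if "r1" in p:
                    f1.write(f"@{rid}/1\n{p['r1']}\n+\n{qual}\n")
                if "r2" in p:
                    f2.write(f"@{rid}/2\n{p['r2']}\n+\n{qual}\n")


def generate_aleseq_reads(
    genome: GenomeSequence, truth: TruthSet, config: SimulationConfig
) -> SimulatedReads:
    """Emit truth alignments: junction fragments from active elements
    (template start in the 5' LTR, end at/near the PBS 3' edge) plus uniform
    background fragments. Fragment sources are recorded in the truth set."""
    rng = np.random.default_rng([config.seed, 1])
    rl = config.read_len
    alignments: List[ReadAlignment] = []
    fragments: List[Fragment] = []
    truth.fragment_sources = {}

    def add_fragment(frag_id: str, chrom: str, tstart: int, tend: int, source: str):
        r1 = GenomicInterval(chrom, tstart, tstart + rl, "+")
        r2 = GenomicInterval(chrom, tend - rl, tend, "-")
        alignments.append(ReadAlignment(frag_id, r1, r2, True))
        alignments.append(ReadAlignment(frag_id, r2, r1, True))
        fragments.append(Fragment(frag_id, GenomicInterval(chrom, tstart, tend), True))
        truth.fragment_sources[frag_id] = source

    for e in truth.elements:
        if not e.active:
            continue
        if e.ltr5 is None or e.pbs is None:
            raise ValueError(f"active element {e.element_id} lacks LTR/PBS truth")
        chrom = e.interval.seq_id
        lo = e.ltr5.start
        hi = max(lo + 1, e.ltr5.end - rl)
        for i in range(config.n_junction_fragments):
            tstart = int(rng.integers(lo, hi))
            tend = int(e.pbs.end + rng.integers(0, 11))
            tend = min(tend, tstart + config.max_template)
            tend = max(tend, tstart + rl)
            add_fragment(f"junc_{e.element_id}_{i:05d}", chrom, tstart, tend,
                         e.element_id)

    chrom_names = [n for n, _ in config.chrom_lengths]
    lengths = np.array([l for _, l in config.chrom_lengths], dtype=float)
    chrom_p = lengths / lengths.sum()
    n_bg = config.n_background_fragments
    if n_bg:
        chrom_idx = rng.choice(len(chrom_names), size=n_bg, p=chrom_p)
        tlens = rng.integers(2 * rl, 301, size=n_bg)
        for i in range(n_bg):
            chrom = chrom_names[chrom_idx[i]]
            L = int(lengths[chrom_idx[i]])
            tlen = int(tlens[i])
            tstart = int(rng.integers(0, L - tlen))
            add_fragment(f"bg_{i:06d}", chrom, tstart, tstart + tlen, "background")

    return SimulatedReads(
        genome=genome, alignments=alignments, fragments=fragments, read_len=rl
    )
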
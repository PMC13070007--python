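"""Amplicon read processing: demultiplex, UMI collapse, translate, classify, tally.

The scFv amplicon is sequenced as an ordered set of short segments (eight in
the reference design) that together cover the CDR windows, with a sample
index barcode and a 14-mer UMI on each cluster.  Reads are demultiplexed by
barcode, collapsed to molecules on (UMI, sequence), translated in frame, and
classified against a :class:`~slisy.library.LibraryDesign`: zero amino-acid
alterations from the round's backbone is the parent, exactly one alteration
matching an enumerated clone is that clone, anything else is unassigned.
Counts per clone and sample feed the enrichment scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .library import DEFAULT_CODON_TABLE, LibraryDesign, reverse_translate

UMI_LENGTH = 14
SAMPLE_ROLES = ("input_library", "trbc2_bound", "trbc1_bound")

#: Standard genetic code, codon -> amino acid, with stops as "*".
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TO_AA.update({codon: "*" for codon in standard_dna_table.stop_codons})


class PipelineError(ValueError):
    """Invalid pipeline configuration (duplicate barcodes, bad layout...)."""


@dataclass(frozen=True, slots=True)
class SegmentRead:
    """One sequencing cluster: sample barcode, UMI and ordered segments."""

    cluster_id: str
    sample_index: str
    umi: str
    segments: tuple[str, ...]

    def __post_init__(self) -> None:
        # only the length is checked here (hot path); an off-alphabet UMI
        # still works as an opaque collapse key
        if len(self.umi) != UMI_LENGTH:
            raise PipelineError(f"UMI must be a {UMI_LENGTH}-mer")


@dataclass(frozen=True)
class Molecule:
    molecule_id: str
    umi: str
    segments: tuple[str, ...]
    n_reads: int            # PCR/optical duplicates collapsed into this molecule


@dataclass(frozen=True)
class CloneAssignment:
    molecule_id: str
    assigned: str           # clone_id | "parent" | "unassigned"
    n_alterations: int


@dataclass
class SegmentLayout:
    """How the sequenced segments tile the concatenated CDR window.

    ``windows`` holds per-segment half-open amino-acid intervals on the
    window peptide (the CDR positions concatenated in sequence order);
    ``trim5``/``trim3`` are nucleotides clipped from each raw segment
    before translation (primer/adapter remnants).
    """

    windows: tuple[tuple[int, int], ...]
    trim5: tuple[int, ...] = ()
    trim3: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.windows)
        if not self.trim5:
            self.trim5 = (0,) * n
        if not self.trim3:
            self.trim3 = (0,) * n
        if len(self.trim5) != n or len(self.trim3) != n:
            raise PipelineError("trim vectors must match segment count")
        expected = 0
        for start, end in self.windows:
            if start != expected or end < start:
                raise PipelineError("segment windows must tile the CDR window in order")
            expected = end

    @property
    def n_segments(self) -> int:
        return len(self.windows)

    @property
    def window_length(self) -> int:
        return self.windows[-1][1] if self.windows else 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"windows": list(map(list, self.windows)),
                 "trim5": list(self.trim5), "trim3": list(self.trim3)},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SegmentLayout":
        data = json.loads(Path(path).read_text())
        return cls(
            windows=tuple(tuple(w) for w in data["windows"]),
            trim5=tuple(data.get("trim5", ())),
            trim3=tuple(data.get("trim3", ())),
        )


def default_layout(design: LibraryDesign, n_segments: int = 8) -> SegmentLayout:
    """Split the design's CDR window into ``n_segments`` near-equal chunks."""
    total = len(design.cdr_positions)
    base, extra = divmod(total, n_segments)
    windows, start = [], 0
    for i in range(n_segments):
        size = base + (1 if i < extra else 0)
        windows.append((start, start + size))
        start += size
    return SegmentLayout(windows=tuple(windows))


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


@dataclass
class DemuxResult:
    by_sample: dict[str, list[SegmentRead]]
    n_discarded: int


def demultiplex(
    reads: list[SegmentRead],
    index_map: dict[str, str] | list[tuple[str, str]],
    max_mismatch: int = 0,
) -> DemuxResult:
    """Assign reads to samples by barcode; ambiguous or distant reads are dropped.

    ``index_map`` maps barcode to sample name, given as a dict or as
    (barcode, sample) pairs; a barcode listed twice is a configuration error.
    """
    if not isinstance(index_map, dict):
        pairs = list(index_map)
        if len({b for b, _ in pairs}) != len(pairs):
            raise PipelineError("duplicate barcode in index map")
        index_map = dict(pairs)
    by_sample: dict[str, list[SegmentRead]] = {s: [] for s in index_map.values()}
    n_discarded = 0
    for read in reads:
        if read.sample_index in index_map:       # exact match fast path
            by_sample[index_map[read.sample_index]].append(read)
            continue
        if max_mismatch == 0:
            n_discarded += 1
            continue
        hits = [
            (d, sample)
            for barcode, sample in index_map.items()
            if (d := _hamming(read.sample_index, barcode)) <= max_mismatch
        ]
        if len(hits) == 1:
            by_sample[hits[0][1]].append(read)
        else:                                    # none, or ambiguous tie
            n_discarded += 1
    return DemuxResult(by_sample=by_sample, n_discarded=n_discarded)


# ---------------------------------------------------------------------------
# UMI collapse
# ---------------------------------------------------------------------------

def collapse_umis(reads: list[SegmentRead]) -> list[Molecule]:
    """Collapse duplicate reads to molecules on the (UMI, full sequence) key.

    Zero UMI mismatch tolerance: the same UMI with a different sequence is a
    distinct molecule (conservative; avoids masking real variants that share
    a UMI by chance or via PCR error).
    """
    groups: dict[tuple[str, tuple[str, ...]], int] = {}
    for read in reads:
        key = (read.umi, read.segments)
        groups[key] = groups.get(key, 0) + 1
    return [
        Molecule(molecule_id=f"{umi}.{i}", umi=umi, segments=segments, n_reads=count)
        for i, ((umi, segments), count) in enumerate(groups.items())
    ]


# ---------------------------------------------------------------------------
# Assembly / translation
# ---------------------------------------------------------------------------

def translate_nt(nt: str) -> str | None:
    """Translate an in-frame nucleotide string; None if untranslatable.

    Untranslatable means a non-ACGT base, a length not divisible by 3, or an
    internal stop codon.
    """
    if len(nt) % 3:
        return None
    aas = []
    for i in range(0, len(nt), 3):
        aa = CODON_TO_AA.get(nt[i : i + 3])
        if aa is None or aa == "*":
            return None
        aas.append(aa)
    return "".join(aas)


def assemble_translate(
    read: SegmentRead | Molecule, layout: SegmentLayout
) -> str | None:
    """Trim, translate and concatenate the segments into the window peptide.

    Returns None for untranslatable molecules (bad base, stop codon, or a
    segment whose trimmed length disagrees with its declared window).
    """
    return _translate_segments(read.segments, layout)


def _translate_segments(
    segments: tuple[str, ...], layout: SegmentLayout
) -> str | None:
    if len(segments) != layout.n_segments:
        raise PipelineError(
            f"read has {len(segments)} segments, layout expects "
            f"{layout.n_segments}"
        )
    parts = []
    for seg, (start, end), t5, t3 in zip(
        segments, layout.windows, layout.trim5, layout.trim3
    ):
        trimmed = seg[t5 : len(seg) - t3 if t3 else len(seg)]
        if len(trimmed) != 3 * (end - start):
            return None
        peptide = translate_nt(trimmed)
        if peptide is None:
            return None
        parts.append(peptide)
    return "".join(parts)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify(
    peptide: str,
    design: LibraryDesign,
    molecule_id: str = "",
    _lookup: dict[tuple[int, str], str] | None = None,
) -> CloneAssignment:
    """Assign a window peptide to a designed clone.

    Zero alterations from the round backbone is the parent entry; exactly
    one alteration that matches an enumerated single-substitution clone is
    that clone; one alteration outside the design, or two or more
    alterations, is unassigned.
    """
    backbone = design.window_peptide()
    if len(peptide) != len(backbone):
        raise PipelineError(
            f"peptide length {len(peptide)} != window length {len(backbone)}"
        )
    diffs = [i for i, (a, b) in enumerate(zip(peptide, backbone)) if a != b]
    if not diffs:
        return CloneAssignment(molecule_id, "parent", 0)
    if len(diffs) == 1:
        lookup = _lookup if _lookup is not None else design.clone_lookup()
        pos = design.cdr_positions[diffs[0]]
        clone_id = lookup.get((pos, peptide[diffs[0]]))
        if clone_id is not None:
            return CloneAssignment(molecule_id, clone_id, 1)
    return CloneAssignment(molecule_id, "unassigned", len(diffs))


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

@dataclass
class CloneCountTable:
    """Per-sample molecule counts per clone, with sample roles and QC totals.

    ``counts`` is indexed by clone_id (including the backbone-only parent
    entry) with one column per sample; ``roles`` maps each sample to
    input_library / trbc2_bound / trbc1_bound.
    """

    counts: pd.DataFrame
    roles: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise PipelineError("negative counts")
        for sample, role in self.roles.items():
            if sample not in self.counts.columns:
                raise PipelineError(f"role given for unknown sample {sample!r}")
            if role not in SAMPLE_ROLES:
                raise PipelineError(f"unknown role {role!r}")

    def sample_for(self, role: str) -> str:
        hits = [s for s, r in self.roles.items() if r == role]
        if len(hits) != 1:
            raise PipelineError(f"expected exactly one {role} sample, got {hits}")
        return hits[0]

    def column(self, role: str) -> pd.Series:
        return self.counts[self.sample_for(role)]

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_csv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "clone_id"
        out.to_csv(path)
        sidecar = Path(path).with_suffix(".meta.json")
        sidecar.write_text(
            json.dumps({"roles": self.roles, "metadata": self.metadata}, indent=2)
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, roles: dict[str, str] | None = None
    ) -> "CloneCountTable":
        counts = pd.read_csv(path, index_col="clone_id")
        metadata: dict = {}
        if roles is None:
            sidecar = Path(path).with_suffix(".meta.json")
            if sidecar.exists():
                data = json.loads(sidecar.read_text())
                roles = data["roles"]
                metadata = data.get("metadata", {})
            else:  # fall back to role-named columns
                roles = {c: c for c in counts.columns if c in SAMPLE_ROLES}
        return cls(counts=counts.astype(int), roles=roles, metadata=metadata)


@dataclass
class QCReport:
    """Conservation accounting per sample; reads in = assigned + every sink."""

    n_input_reads: int
    n_discarded_reads: int
    per_sample: dict[str, dict[str, int]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_input_reads": self.n_input_reads,
                    "n_discarded_reads": self.n_discarded_reads,
                    "per_sample": self.per_sample,
                },
                indent=2,
            )
        )


def _counts_frame(
    per_sample_counters: dict[str, dict[str, int]], design: LibraryDesign
) -> pd.DataFrame:
    index = [c.clone_id for c in design.clones]
    parent_id = design.parent_entry.clone_id
    data = {}
    for sample, counter in per_sample_counters.items():
        col = dict.fromkeys(index, 0)
        for assigned, n in counter.items():
            clone_id = parent_id if assigned == "parent" else assigned
            col[clone_id] += n
        data[sample] = col
    return pd.DataFrame(data, index=index, dtype=int)


def tally(
    assignments_by_sample: dict[str, list[CloneAssignment]],
    design: LibraryDesign,
    roles: dict[str, str],
) -> CloneCountTable:
    """Count assigned molecules per clone and sample; unassigned are excluded."""
    counters: dict[str, dict[str, int]] = {}
    for sample, assignments in assignments_by_sample.items():
        counter: dict[str, int] = {}
        for a in assignments:
            if a.assigned == "unassigned":
                continue
            counter[a.assigned] = counter.get(a.assigned, 0) + 1
        counters[sample] = counter
    return CloneCountTable(counts=_counts_frame(counters, design), roles=roles)


def count_reads(
    reads: list[SegmentRead],
    design: LibraryDesign,
    index_map: dict[str, str],
    roles: dict[str, str],
    layout: SegmentLayout | None = None,
    max_mismatch: int = 0,
    count_molecules: bool = True,
) -> tuple[CloneCountTable, QCReport]:
    """Full pipeline: demultiplex -> collapse -> translate -> classify -> tally.

    With ``count_molecules`` off, duplicate reads are counted individually
    instead of once per UMI-collapsed molecule.
    """
    if layout is None:
        layout = default_layout(design)
    demux = demultiplex(reads, index_map, max_mismatch=max_mismatch)
    lookup = design.clone_lookup()
    # most molecules repeat a designed sequence; cache per distinct segments
    cache: dict[tuple[str, ...], tuple[str, int] | None] = {}
    counters: dict[str, dict[str, int]] = {}
    per_sample: dict[str, dict[str, int]] = {}
    for sample, sample_reads in demux.by_sample.items():
        # inline UMI collapse: (umi, segments) -> duplicate read count
        groups: dict[tuple[str, tuple[str, ...]], int] = {}
        for read in sample_reads:
            key = (read.umi, read.segments)
            groups[key] = groups.get(key, 0) + 1
        qc = {
            "reads": len(sample_reads),
            "molecules": len(groups),
            "assigned": 0,
            "unassigned": 0,
            "untranslatable": 0,
        }
        counter: dict[str, int] = {}
        for (_, segments), n_reads in groups.items():
            weight = 1 if count_molecules else n_reads
            hit = cache.get(segments, "MISS")
            if hit == "MISS":
                peptide = _translate_segments(segments, layout)
                if peptide is None:
                    hit = None
                else:
                    a = classify(peptide, design, _lookup=lookup)
                    hit = (a.assigned, a.n_alterations)
                cache[segments] = hit
            if hit is None:
                qc["untranslatable"] += weight
                continue
            assigned, _ = hit
            if assigned == "unassigned":
                qc["unassigned"] += weight
            else:
                qc["assigned"] += weight
                counter[assigned] = counter.get(assigned, 0) + weight
        counters[sample] = counter
        per_sample[sample] = qc
    table = CloneCountTable(counts=_counts_frame(counters, design), roles=roles)
    qc_report = QCReport(
        n_input_reads=len(reads),
        n_discarded_reads=demux.n_discarded,
        per_sample=per_sample,
    )
    table.metadata["qc"] = per_sample
    return table, qc_report


# ---------------------------------------------------------------------------
# TSV record interface
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path) -> list[SegmentRead]:
    """Load reads from the TSV record format (cluster_id, sample_index, umi, seg1..N)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    seg_cols = [c for c in df.columns if c.startswith("seg")]
    return [
        SegmentRead(
            cluster_id=row.cluster_id,
            sample_index=row.sample_index,
            umi=row.umi,
            segments=tuple(getattr(row, c) for c in seg_cols),
        )
        for row in df.itertuples(index=False)
    ]


def write_tsv(reads: list[SegmentRead], path: str | Path) -> None:
    if not reads:
        Path(path).write_text("cluster_id\tsample_index\tumi\n")
        return
    n_seg = len(reads[0].segments)
    cols = ["cluster_id", "sample_index", "umi"] + [f"seg{i+1}" for i in range(n_seg)]
    rows = [(r.cluster_id, r.sample_index, r.umi, *r.segments) for r in reads]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def clone_window_nt(design: LibraryDesign, clone_aa_sequence: str) -> str:
    """Nucleotide encoding of a clone's CDR window (fixed codon per residue)."""
    return reverse_translate(
        design.window_peptide(clone_aa_sequence), DEFAULT_CODON_TABLE
    )
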
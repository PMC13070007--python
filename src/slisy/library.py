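"""Site-saturation scFv variant library design.

A parent scFv with annotated CDR intervals is expanded into a library of
single-substitution variants: every labelled CDR position is replaced, one
at a time, by each allowed non-parental amino acid.  Affinity maturation
proceeds in rounds: the best clone of one round becomes the fixed
"backbone" of the next, its positions are frozen, and the remaining sites
are saturated again, so a round-``k`` clone carries ``k`` cumulative
substitutions.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
CDR_NAMES = ("L1", "L2", "L3", "H1", "H2", "H3")

#: One fixed codon per amino acid (E. coli high-usage codons); any valid
#: encoding suffices because the translated sequence is what is screened.
DEFAULT_CODON_TABLE = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}


class DesignError(ValueError):
    """Invalid library configuration (bad intervals, overlapping backbone...)."""


@dataclass(frozen=True)
class Substitution:
    """A single amino-acid replacement at one scFv position."""

    seq_index: int          # 0-based index on the scFv amino-acid sequence
    parent_aa: str
    new_aa: str
    label: str              # user-facing position label, opaque (e.g. "30")
    cdr: str                # CDR the position belongs to ("L1".."H3")

    @property
    def token(self) -> str:
        """Mutation token in ``<parentAA><label><newAA>`` form, e.g. ``V30K``."""
        return f"{self.parent_aa}{self.label}{self.new_aa}"

    @property
    def sort_key(self) -> tuple[int, int]:
        # light-chain sites before heavy-chain, then ascending position
        return (0 if self.cdr.startswith("L") else 1, self.seq_index)


@dataclass(frozen=True)
class SiteSpec:
    """A mutable CDR position and its allowed substitutions."""

    position_label: str
    seq_index: int
    parent_aa: str
    allowed_substitutions: frozenset[str]
    cdr: str

    def __post_init__(self) -> None:
        if self.parent_aa in self.allowed_substitutions:
            raise DesignError(
                f"site {self.position_label}: parent residue "
                f"{self.parent_aa} cannot be its own substitution"
            )
        bad = set(self.allowed_substitutions) - set(CANONICAL_AA)
        if bad:
            raise DesignError(f"site {self.position_label}: non-canonical {bad}")


@dataclass
class ParentScFv:
    """Parent scFv sequence with CDR annotations.

    ``cdr_intervals`` are 0-based half-open ``(name, start, end)`` on the
    amino-acid sequence; ``position_labels`` maps a sequence index to the
    display label used in mutation strings.  Every labelled position must
    fall inside a CDR interval.
    """

    id: str
    aa_sequence: str
    cdr_intervals: list[tuple[str, int, int]]
    position_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.aa_sequence) - set(CANONICAL_AA)
        if bad:
            raise DesignError(f"non-canonical residues in parent: {bad}")
        spans: list[tuple[int, int]] = []
        for name, start, end in self.cdr_intervals:
            if name not in CDR_NAMES:
                raise DesignError(f"unknown CDR name {name!r}")
            if not (0 <= start < end <= len(self.aa_sequence)):
                raise DesignError(f"CDR {name} interval [{start},{end}) out of bounds")
            spans.append((start, end))
        spans.sort()
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise DesignError("CDR intervals overlap")
        for idx in self.position_labels:
            if self.cdr_of(idx) is None:
                raise DesignError(f"labelled position {idx} lies outside all CDRs")

    def cdr_of(self, seq_index: int) -> str | None:
        for name, start, end in self.cdr_intervals:
            if start <= seq_index < end:
                return name
        return None

    @property
    def label_to_index(self) -> dict[str, int]:
        return {lab: idx for idx, lab in self.position_labels.items()}


@dataclass(frozen=True)
class VariantClone:
    """One library member: the backbone plus at most one new substitution."""

    clone_id: str
    backbone_substitutions: tuple[Substitution, ...]
    new_substitution: Substitution | None
    aa_sequence: str

    @property
    def all_substitutions(self) -> tuple[Substitution, ...]:
        subs = self.backbone_substitutions
        if self.new_substitution is not None:
            subs = subs + (self.new_substitution,)
        return subs


def _apply_substitutions(sequence: str, subs: tuple[Substitution, ...]) -> str:
    chars = list(sequence)
    for sub in subs:
        if chars[sub.seq_index] != sub.parent_aa:
            raise DesignError(
                f"substitution {sub.token}: residue at index {sub.seq_index} "
                f"is {chars[sub.seq_index]}, not {sub.parent_aa}"
            )
        chars[sub.seq_index] = sub.new_aa
    return "".join(chars)


def _mutation_string(subs: tuple[Substitution, ...]) -> str:
    ordered = sorted(subs, key=lambda s: s.sort_key)
    return ",".join(s.token for s in ordered)


@dataclass
class LibraryDesign:
    """A single saturation round: backbone, remaining sites, enumerated clones."""

    round_number: int
    parent: ParentScFv
    backbone: tuple[Substitution, ...]
    sites: tuple[SiteSpec, ...]
    clones: tuple[VariantClone, ...]

    @property
    def backbone_sequence(self) -> str:
        return _apply_substitutions(self.parent.aa_sequence, self.backbone)

    @property
    def parent_entry(self) -> VariantClone:
        return self.clones[0]

    @property
    def variants(self) -> tuple[VariantClone, ...]:
        """Clones excluding the backbone-only parent entry."""
        return self.clones[1:]

    @property
    def cdr_positions(self) -> tuple[int, ...]:
        """All CDR sequence indices, ascending; the clone-identifying window."""
        pos: list[int] = []
        for _, start, end in sorted(self.parent.cdr_intervals, key=lambda t: t[1]):
            pos.extend(range(start, end))
        return tuple(pos)

    def window_peptide(self, aa_sequence: str | None = None) -> str:
        """Residues of ``aa_sequence`` (default: backbone) at the CDR positions."""
        seq = self.backbone_sequence if aa_sequence is None else aa_sequence
        return "".join(seq[i] for i in self.cdr_positions)

    def clone_lookup(self) -> dict[tuple[int, str], str]:
        """Map ``(seq_index, new_aa)`` of the novel substitution to clone_id."""
        table: dict[tuple[int, str], str] = {}
        for clone in self.variants:
            sub = clone.new_substitution
            assert sub is not None
            table[(sub.seq_index, sub.new_aa)] = clone.clone_id
        return table


def enumerate_sites(
    parent: ParentScFv,
    exclusions: dict[str, set[str]] | None = None,
) -> list[SiteSpec]:
    """One :class:`SiteSpec` per labelled CDR position.

    ``exclusions`` maps a position label to amino acids withheld from
    saturation at that site (mirroring manual curation of low-diversity or
    unusual residues); a fully excluded site yields no SiteSpec.
    """
    exclusions = exclusions or {}
    unknown = set(exclusions) - set(parent.position_labels.values())
    if unknown:
        raise DesignError(f"exclusion labels not in parent: {sorted(unknown)}")
    sites = []
    for seq_index in sorted(parent.position_labels):
        label = parent.position_labels[seq_index]
        parent_aa = parent.aa_sequence[seq_index]
        allowed = set(CANONICAL_AA) - {parent_aa} - set(exclusions.get(label, ()))
        if not allowed:
            continue
        sites.append(
            SiteSpec(
                position_label=label,
                seq_index=seq_index,
                parent_aa=parent_aa,
                allowed_substitutions=frozenset(allowed),
                cdr=parent.cdr_of(seq_index),  # type: ignore[arg-type]
            )
        )
    return sites


def build_library(
    round_number: int,
    parent: ParentScFv,
    backbone: tuple[Substitution, ...] | list[Substitution] = (),
    sites: list[SiteSpec] | None = None,
) -> LibraryDesign:
    """Enumerate the saturation library for one round.

    Clones are generated deterministically in (site order, alphabetical
    amino acid) order; the first entry is the backbone-only parent.  The
    variant count is ``sum(len(s.allowed_substitutions) for s in sites)``.
    """
    backbone = tuple(backbone)
    if sites is None:
        sites = enumerate_sites(parent)
    backbone_positions = {s.seq_index for s in backbone}
    overlap = [s for s in sites if s.seq_index in backbone_positions]
    if overlap:
        raise DesignError(
            f"sites overlap backbone positions: "
            f"{[s.position_label for s in overlap]}"
        )
    backbone_seq = _apply_substitutions(parent.aa_sequence, backbone)

    parent_id = _mutation_string(backbone) if backbone else "parent"
    clones = [
        VariantClone(
            clone_id=parent_id,
            backbone_substitutions=backbone,
            new_substitution=None,
            aa_sequence=backbone_seq,
        )
    ]
    seen = {parent_id}
    for site in sorted(sites, key=lambda s: s.seq_index):
        for new_aa in sorted(site.allowed_substitutions):
            sub = Substitution(
                seq_index=site.seq_index,
                parent_aa=site.parent_aa,
                new_aa=new_aa,
                label=site.position_label,
                cdr=site.cdr,
            )
            clone_id = _mutation_string(backbone + (sub,))
            if clone_id in seen:
                raise DesignError(f"duplicate clone id {clone_id}")
            seen.add(clone_id)
            chars = list(backbone_seq)
            chars[sub.seq_index] = new_aa
            clones.append(
                VariantClone(
                    clone_id=clone_id,
                    backbone_substitutions=backbone,
                    new_substitution=sub,
                    aa_sequence="".join(chars),
                )
            )
    return LibraryDesign(
        round_number=round_number,
        parent=parent,
        backbone=backbone,
        sites=tuple(sorted(sites, key=lambda s: s.seq_index)),
        clones=tuple(clones),
    )


def apply_backbone(design: LibraryDesign, selected: VariantClone) -> LibraryDesign:
    """Fix ``selected``'s substitutions and enumerate the next round.

    The selected clone's cumulative substitutions become the new backbone;
    their positions are removed from the mutable sites and the round number
    is incremented.  Selecting the parent entry leaves the sites unchanged.
    """
    if selected.clone_id not in {c.clone_id for c in design.clones}:
        raise DesignError(f"clone {selected.clone_id!r} is not in this design")
    new_backbone = selected.all_substitutions
    frozen = {s.seq_index for s in new_backbone}
    remaining = [s for s in design.sites if s.seq_index not in frozen]
    return build_library(
        round_number=design.round_number + 1,
        parent=design.parent,
        backbone=new_backbone,
        sites=remaining,
    )


def reverse_translate(
    aa_sequence: str | VariantClone,
    codon_table: dict[str, str] = DEFAULT_CODON_TABLE,
) -> str:
    """Encode an amino-acid sequence with one fixed codon per residue."""
    if isinstance(aa_sequence, VariantClone):
        aa_sequence = aa_sequence.aa_sequence
    missing = set(aa_sequence) - set(codon_table)
    if missing:
        raise DesignError(f"codon table lacks {sorted(missing)}")
    return "".join(codon_table[aa] for aa in aa_sequence)


# ---------------------------------------------------------------------------
# File interfaces: parent FASTA + CDR TSV in, library FASTA/CSV out
# ---------------------------------------------------------------------------

def read_parent(fasta_path: str | Path, cdr_tsv_path: str | Path) -> ParentScFv:
    """Load a parent scFv from FASTA plus a CDR interval table.

    The TSV has columns ``cdr_name``, ``start``, ``end``, ``label`` — one
    row per CDR, coordinates 0-based half-open, ``label`` a comma-joined
    list of per-position display labels (empty = 1-based sequence indices).
    """
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    intervals: list[tuple[str, int, int]] = []
    labels: dict[int, str] = {}
    with open(cdr_tsv_path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            name, start, end = row["cdr_name"], int(row["start"]), int(row["end"])
            intervals.append((name, start, end))
            raw = (row.get("label") or "").strip()
            row_labels = raw.split(",") if raw else [str(i + 1) for i in range(start, end)]
            if len(row_labels) != end - start:
                raise DesignError(
                    f"CDR {name}: {len(row_labels)} labels for {end - start} positions"
                )
            for offset, lab in enumerate(row_labels):
                labels[start + offset] = lab.strip()
    return ParentScFv(
        id=record.id,
        aa_sequence=str(record.seq),
        cdr_intervals=intervals,
        position_labels=labels,
    )


def write_library(design: LibraryDesign, outdir: str | Path) -> None:
    """Write amino-acid and nucleotide FASTA plus a CSV manifest.

    The directory is self-contained: the parent FASTA and CDR TSV are
    included so the design can be rebuilt for read classification.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    parent = design.parent
    SeqIO.write(
        [SeqRecord(Seq(parent.aa_sequence), id=parent.id, description="")],
        str(outdir / "parent.fasta"),
        "fasta",
    )
    with open(outdir / "cdrs.tsv", "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["cdr_name", "start", "end", "label"])
        for name, start, end in parent.cdr_intervals:
            labels = ",".join(
                parent.position_labels.get(i, str(i + 1)) for i in range(start, end)
            )
            writer.writerow([name, start, end, labels])
    aa_records = [
        SeqRecord(Seq(c.aa_sequence), id=c.clone_id, description="")
        for c in design.clones
    ]
    nt_records = [
        SeqRecord(Seq(reverse_translate(c.aa_sequence)), id=c.clone_id, description="")
        for c in design.clones
    ]
    SeqIO.write(aa_records, str(outdir / "library_aa.fasta"), "fasta")
    SeqIO.write(nt_records, str(outdir / "library_nt.fasta"), "fasta")
    with open(outdir / "manifest.csv", "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["clone_id", "substitutions", "aa_sequence"])
        for c in design.clones:
            writer.writerow(
                [c.clone_id, _mutation_string(c.all_substitutions), c.aa_sequence]
            )
    meta = {
        "round_number": design.round_number,
        "parent_id": design.parent.id,
        "backbone": [s.token for s in design.backbone],
        "n_sites": len(design.sites),
        "n_variants": len(design.variants),
    }
    (outdir / "design.json").write_text(json.dumps(meta, indent=2))


def parse_mutation_string(parent: ParentScFv, text: str) -> tuple[Substitution, ...]:
    """Parse ``"V30K,S32R"`` against the parent's position labels."""
    subs = []
    lookup = parent.label_to_index
    for token in [t.strip() for t in text.split(",") if t.strip()]:
        parent_aa, label, new_aa = token[0], token[1:-1], token[-1]
        if label not in lookup:
            raise DesignError(f"unknown position label in token {token!r}")
        idx = lookup[label]
        if parent.aa_sequence[idx] != parent_aa:
            raise DesignError(
                f"token {token!r}: parent residue at {label} is "
                f"{parent.aa_sequence[idx]}"
            )
        subs.append(
            Substitution(
                seq_index=idx,
                parent_aa=parent_aa,
                new_aa=new_aa,
                label=label,
                cdr=parent.cdr_of(idx),  # type: ignore[arg-type]
            )
        )
    return tuple(subs)
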
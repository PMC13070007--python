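"""Synthetic inputs with the statistical structure the pipeline assumes.

Panning of a phage library over TRBC2+ vs TRBC1+ cells is modelled as
multinomial sampling: each clone has an input-library fraction ``f_i`` and
per-cell-line capture probabilities ``p2_i``, ``p1_i``; the bound pools are
multinomial draws with proportions proportional to ``f_i * p_i``.
Sequencing is emulated by emitting one segmented amplicon record per
molecule with a fresh random 14-mer UMI, geometric PCR duplication and
per-base substitution errors.  Flow-cytometry quadrant tables and noisy 4PL
dose-response curves cover the downstream assay metrics.

All generators take an explicit seed and record it in output metadata, so
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assays import FlowQuadrantCounts, FourPLFit, PatientFlowCounts, four_pl
from .library import (
    CANONICAL_AA,
    LibraryDesign,
    ParentScFv,
    build_library,
    enumerate_sites,
)
from .reads import (
    CloneCountTable,
    SegmentLayout,
    SegmentRead,
    clone_window_nt,
    default_layout,
)

class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reference parents
# ---------------------------------------------------------------------------

def example_parent(seed: int = 2024) -> ParentScFv:
    """Synthetic parent scFv with 74 labelled CDR positions.

    A stand-in sequence (the real parent antibody sequence is not public)
    with six CDRs of lengths 11/7/9 (light chain) and 10/17/20 (heavy
    chain) — 74 saturable sites in total, the reference configuration that
    enumerates 74 x 19 = 1,406 single-substitution variants.  Labels are
    1-based sequence positions.
    """
    rng = np.random.default_rng(seed)
    length = 240
    seq = "".join(rng.choice(list(CANONICAL_AA), size=length))
    cdr_specs = [  # (name, start); light chain first, as in a VL-VH scFv
        ("L1", 25, 11), ("L2", 49, 7), ("L3", 88, 9),
        ("H1", 145, 10), ("H2", 170, 17), ("H3", 210, 20),
    ]
    intervals = [(name, start, start + size) for name, start, size in cdr_specs]
    labels = {
        i: str(i + 1) for _, start, end in intervals for i in range(start, end)
    }
    return ParentScFv(
        id="synthetic-parent-scFv",
        aa_sequence=seq,
        cdr_intervals=intervals,
        position_labels=labels,
    )


def toy_parent(n_sites: int = 8, seed: int = 7) -> ParentScFv:
    """Small parent (single CDR of ``n_sites`` positions) for fast end-to-end runs."""
    rng = np.random.default_rng(seed)
    length = max(n_sites + 10, 20)
    seq = "".join(rng.choice(list(CANONICAL_AA), size=length))
    start = 5
    intervals = [("H3", start, start + n_sites)]
    labels = {i: str(i + 1) for i in range(start, start + n_sites)}
    return ParentScFv(
        id=f"toy-parent-{n_sites}",
        aa_sequence=seq,
        cdr_intervals=intervals,
        position_labels=labels,
    )


# ---------------------------------------------------------------------------
# Panning
# ---------------------------------------------------------------------------

@dataclass
class PanningTruth:
    """Ground truth: input fractions and capture probabilities per clone."""

    clone_ids: list[str]
    input_fractions: np.ndarray
    p2: np.ndarray          # capture probability on TRBC2+ cells, in (0, 1]
    p1: np.ndarray          # capture probability on TRBC1+ cells, in (0, 1]

    def __post_init__(self) -> None:
        self.input_fractions = np.asarray(self.input_fractions, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        n = len(self.clone_ids)
        if not (len(self.input_fractions) == len(self.p2) == len(self.p1) == n):
            raise SimulationError("truth arrays must match clone_ids length")
        if (self.input_fractions < 0).any() or not np.isclose(
            self.input_fractions.sum(), 1.0
        ):
            raise SimulationError("input fractions must form a simplex")
        for p in (self.p2, self.p1):
            if (p <= 0).any() or (p > 1).any():
                raise SimulationError("capture probabilities must lie in (0, 1]")

    @classmethod
    def uniform_with_hot_clone(
        cls,
        design: LibraryDesign,
        hot_clone: str,
        p_base: float = 0.02,
        selectivity: float = 10.0,
    ) -> "PanningTruth":
        """Equal input fractions; one clone's TRBC2 capture is ``selectivity``-fold higher."""
        ids = [c.clone_id for c in design.clones]
        if hot_clone not in ids:
            raise SimulationError(f"{hot_clone!r} is not in the design")
        n = len(ids)
        p2 = np.full(n, p_base)
        p2[ids.index(hot_clone)] = min(1.0, selectivity * p_base)
        return cls(
            clone_ids=ids,
            input_fractions=np.full(n, 1.0 / n),
            p2=p2,
            p1=np.full(n, p_base),
        )


def capture_from_affinity(concentration_M: float, ka_eq: float) -> float:
    """Optional affinity link: equilibrium occupancy C*KA / (1 + C*KA)."""
    if concentration_M < 0 or ka_eq < 0:
        raise SimulationError("concentration and KA must be non-negative")
    x = concentration_M * ka_eq
    return x / (1.0 + x)


@dataclass
class SimConfig:
    """Sequencing-emulation knobs: depth, error rate, duplication, seed."""

    depth: int = 100_000
    error_rate: float = 0.001       # per-base substitution probability
    umi_dup_mean: float = 2.0       # geometric mean reads per molecule, >= 1
    seed: int = 0
    sample_names: tuple[str, str, str] = ("input", "trbc2", "trbc1")

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise SimulationError("depth must be non-negative")
        if not (0.0 <= self.error_rate <= 0.05):
            raise SimulationError("error rate must lie in [0, 0.05]")
        if self.umi_dup_mean < 1:
            raise SimulationError("duplication mean must be >= 1")

    @property
    def roles(self) -> dict[str, str]:
        names = self.sample_names
        return {
            names[0]: "input_library",
            names[1]: "trbc2_bound",
            names[2]: "trbc1_bound",
        }


def simulate_panning(
    truth: PanningTruth,
    config: SimConfig,
    design: LibraryDesign | None = None,
) -> CloneCountTable:
    """Multinomial molecule counts for input, TRBC2-bound and TRBC1-bound pools.

    The bound-pool proportions are ``f_i * p_i`` renormalized; each sample
    is an independent multinomial of size ``config.depth``.
    """
    rng = np.random.default_rng(config.seed)
    f = truth.input_fractions
    q2 = f * truth.p2
    q2 = q2 / q2.sum()
    q1 = f * truth.p1
    q1 = q1 / q1.sum()
    names = config.sample_names
    counts = pd.DataFrame(
        {
            names[0]: rng.multinomial(config.depth, f),
            names[1]: rng.multinomial(config.depth, q2),
            names[2]: rng.multinomial(config.depth, q1),
        },
        index=pd.Index(truth.clone_ids, name="clone_id"),
    )
    if design is not None:  # keep full design index, zero-filled
        full = pd.Index([c.clone_id for c in design.clones], name="clone_id")
        counts = counts.reindex(full, fill_value=0)
    return CloneCountTable(
        counts=counts,
        roles=config.roles,
        metadata={"seed": config.seed, "depth": config.depth},
    )


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

def _random_umis(rng: np.random.Generator, n: int) -> list[str]:
    if n == 0:
        return []
    codes = rng.integers(0, 4, size=(n, 14))
    blob = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes()
    return [blob[i : i + 14].decode("ascii") for i in range(0, 14 * n, 14)]


def emit_reads(
    table: CloneCountTable,
    design: LibraryDesign,
    config: SimConfig,
    layout: SegmentLayout | None = None,
    index_map: dict[str, str] | None = None,
) -> list[SegmentRead]:
    """Emit segmented amplicon reads realizing a count table.

    One molecule per counted unit with a fresh random UMI; geometric PCR
    duplication (mean ``umi_dup_mean``); independent per-base substitution
    errors at ``error_rate`` applied per read.  With error rate 0 and
    duplication mean 1 the read pipeline tallies back to ``table`` exactly.
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of panning draw
    if layout is None:
        layout = default_layout(design)
    if index_map is None:
        index_map = {
            barcode: sample
            for barcode, sample in zip(
                ("ACGTAC", "TGCATG", "GTACGT", "CATCAT", "GGATCC", "TTAACC"),
                table.counts.columns,
            )
        }
    sample_to_barcode = {s: b for b, s in index_map.items()}
    seg_bounds = [(3 * start, 3 * end) for start, end in layout.windows]
    clone_ids = list(table.counts.index)
    window_nt = {
        c.clone_id: clone_window_nt(design, c.aa_sequence) for c in design.clones
    }
    # error-free reads of one clone share a single pre-sliced segment tuple
    base_segments = {
        cid: tuple(window_nt[cid][a:b] for a, b in seg_bounds) for cid in clone_ids
    }
    length = len(next(iter(window_nt.values()))) if window_nt else 0
    reads: list[SegmentRead] = []
    cluster = 0
    for sample in table.counts.columns:
        barcode = sample_to_barcode[sample]
        counts_arr = table.counts[sample].to_numpy()
        mol_clone = np.repeat(np.arange(len(clone_ids)), counts_arr)
        n_mol = int(mol_clone.size)
        if n_mol == 0:
            continue
        umis = _random_umis(rng, n_mol)
        if config.umi_dup_mean > 1:
            dups = rng.geometric(1.0 / config.umi_dup_mean, size=n_mol)
        else:
            dups = np.ones(n_mol, dtype=int)
        read_mol = np.repeat(np.arange(n_mol), dups)
        n_reads = int(read_mol.size)
        if config.error_rate > 0 and length:
            n_err = rng.binomial(length, config.error_rate, size=n_reads)
        else:
            n_err = np.zeros(n_reads, dtype=int)
        mol_clone_l = mol_clone.tolist()
        read_mol_l = read_mol.tolist()
        err_rows: dict[int, tuple[str, ...]] = {}
        err_idx = np.nonzero(n_err)[0]
        if err_idx.size:
            total_err = int(n_err[err_idx].sum())
            err_pos = rng.integers(0, length, size=total_err).tolist()
            err_off = rng.integers(0, 3, size=total_err).tolist()
            cursor = 0
            for row in err_idx.tolist():
                cid = clone_ids[mol_clone_l[read_mol_l[row]]]
                chars = list(window_nt[cid])
                for _ in range(int(n_err[row])):
                    pos = err_pos[cursor]
                    chars[pos] = "ACGT".replace(chars[pos], "")[err_off[cursor]]
                    cursor += 1
                nt = "".join(chars)
                err_rows[row] = tuple(nt[a:b] for a, b in seg_bounds)
        for row, mol in enumerate(read_mol_l):
            segments = err_rows.get(row) or base_segments[clone_ids[mol_clone_l[mol]]]
            reads.append(
                SegmentRead(
                    cluster_id=f"c{cluster}",
                    sample_index=barcode,
                    umi=umis[mol],
                    segments=segments,
                )
            )
            cluster += 1
    return reads


# ---------------------------------------------------------------------------
# Flow and dose-response tables
# ---------------------------------------------------------------------------

def simulate_flow_quadrants(
    composition: tuple[float, float, float, float],
    n_cells: int,
    seed: int = 0,
) -> FlowQuadrantCounts:
    """Multinomial quadrant counts; ``composition`` orders (trbc1, trbc2, dual+, dual-)."""
    comp = np.asarray(composition, dtype=float)
    if (comp < 0).any() or not np.isclose(comp.sum(), 1.0):
        raise SimulationError("composition must form a simplex")
    rng = np.random.default_rng(seed)
    c1, c2, dp, dn = rng.multinomial(n_cells, comp)
    return FlowQuadrantCounts(
        trbc1_only=int(c1), trbc2_only=int(c2), dual_pos=int(dp), dual_neg=int(dn)
    )


def simulate_patient_flow(
    malignant_fraction: float,
    total_T: int,
    trbc2_fraction_of_normal: float = 0.6,
    seed: int = 0,
) -> PatientFlowCounts:
    """Patient T-cell counts with a given malignant (TRBC2+CD26-) fraction."""
    if not (0.0 <= malignant_fraction <= 1.0):
        raise SimulationError("malignant fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cancer = int(rng.binomial(total_T, malignant_fraction))
    normal = total_T - cancer
    normal_trbc2 = int(rng.binomial(normal, trbc2_fraction_of_normal))
    return PatientFlowCounts(
        cancer=cancer,
        normal_trbc2=normal_trbc2,
        normal_trbc1=normal - normal_trbc2,
        total_T=total_T,
    )


def simulate_dose_response(
    params: FourPLFit,
    doses,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """4PL responses at the given doses plus additive Gaussian noise."""
    rng = np.random.default_rng(seed)
    x = np.asarray(doses, dtype=float)
    y = four_pl(x, params.top, params.bottom, params.hill, params.ic50)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return pd.DataFrame({"dose": x, "response": y, "seed": seed})


# ---------------------------------------------------------------------------
# Convenience: toy design for end-to-end runs
# ---------------------------------------------------------------------------

def toy_design(n_sites: int = 8, seed: int = 7) -> LibraryDesign:
    parent = toy_parent(n_sites=n_sites, seed=seed)
    return build_library(1, parent, sites=enumerate_sites(parent))
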
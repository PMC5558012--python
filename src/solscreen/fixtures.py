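"""Synthetic data generators: antibody libraries with controlled mutation
structure, PEG-precipitation panels, and coarse-grained toy structures.

Real antibody screening data are rarely shareable, so every analysis in
this package can be exercised on synthetic inputs whose *structure*
mirrors a realistic nine-variant screening panel: a parent antibody plus
eight derivatives carrying targeted mutations in the variable domains,
with pairwise mutation totals spanning 5 to 32 (median 19); sigmoidal
PEG-precipitation curves with Gaussian replicate noise; and idealized
helix / sheet / globule structures for exposure and hotspot tests.

All generators are pure functions of (spec, seed).

Library construction is constructive, not rejection-sampled: each variant
mutates its own disjoint set of positions (to residues different from the
parent), so the mutation count between variants a and b is exactly
k_a + k_b, and the distance to the parent is exactly k_v.  Requested
distance matrices that cannot be written this way are rejected loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .seqio import Chain, ChainRole, MutationTable, STANDARD_AA, mutation_table
from .peg_assay import PEGSeries, sigmoid
from .structural import StructureModel, _ONE_TO_THREE
from .scoring import HUMAN_PROTEOME_FREQS

# Per-variant mutation counts (relative to the parent, variant 1) whose
# induced pairwise totals k_a + k_b have minimum 5 (variants 1 & 7),
# unique maximum 32 (variants 3 & 9) and median 19 over all 36 pairs.
DEFAULT_MUTATION_COUNTS = (0, 7, 14, 13, 8, 6, 5, 13, 18)

DEFAULT_LIBRARY_SEED = 7


@dataclass(frozen=True)
class LibrarySpec:
    """Specification of a synthetic antibody library.

    `mutation_counts[v]` is the number of positions at which variant v
    differs from the parent (variant 0); mutated position sets are
    disjoint across variants, so the pairwise distance matrix is
    d(a, b) = counts[a] + counts[b] (counts[0] = 0 for the parent).
    `heavy_fraction` of each variant's mutations land on the heavy chain,
    emulating panels where most diversity sits in the VH domain.
    """

    vh_length: int = 120
    vl_length: int = 110
    mutation_counts: tuple = DEFAULT_MUTATION_COUNTS
    heavy_fraction: float = 0.7
    seed: int = DEFAULT_LIBRARY_SEED
    id_prefix: str = "mAb"

    def __post_init__(self):
        if self.mutation_counts[0] != 0:
            raise ValueError("the first variant is the parent: counts[0] must be 0")
        if any(k < 0 for k in self.mutation_counts):
            raise ValueError("mutation counts must be nonnegative")

    @property
    def n_variants(self) -> int:
        return len(self.mutation_counts)

    def target_distance(self, a: int, b: int) -> int:
        if a == b:
            return 0
        return self.mutation_counts[a] + self.mutation_counts[b]


DEFAULT_LIBRARY_SPEC = LibrarySpec()


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    aas = np.array(list(STANDARD_AA))
    p = np.array([HUMAN_PROTEOME_FREQS[a] for a in STANDARD_AA])
    return "".join(rng.choice(aas, size=length, p=p / p.sum()))


def generate_library(
    spec: LibrarySpec = DEFAULT_LIBRARY_SPEC,
) -> tuple[list[tuple[Chain, Chain]], MutationTable]:
    """Generate a parent + variants library with exact pairwise distances.

    Returns (variants, table): one (heavy, light) chain pair per variant
    (the parent first) and the realized pairwise mutation table, which by
    construction matches `spec.target_distance` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    heavy_needed = sum(
        round(spec.heavy_fraction * k) for k in spec.mutation_counts
    )
    light_needed = sum(spec.mutation_counts) - heavy_needed
    if heavy_needed > spec.vh_length or light_needed > spec.vl_length:
        raise ValueError(
            "infeasible spec: disjoint mutation sets need "
            f"{heavy_needed} heavy and {light_needed} light positions, "
            f"chains have {spec.vh_length} / {spec.vl_length}"
        )

    parent_vh = _random_sequence(rng, spec.vh_length)
    parent_vl = _random_sequence(rng, spec.vl_length)
    heavy_pool = list(rng.permutation(spec.vh_length))
    light_pool = list(rng.permutation(spec.vl_length))

    variants = []
    for v, k in enumerate(spec.mutation_counts):
        vid = f"{spec.id_prefix}{v + 1}"
        kh = round(spec.heavy_fraction * k)
        kl = k - kh
        vh = list(parent_vh)
        vl = list(parent_vl)
        for _ in range(kh):
            pos = heavy_pool.pop()
            vh[pos] = _mutate(rng, vh[pos])
        for _ in range(kl):
            pos = light_pool.pop()
            vl[pos] = _mutate(rng, vl[pos])
        variants.append(
            (
                Chain(id=f"{vid}_VH", sequence="".join(vh), role=ChainRole.HEAVY),
                Chain(id=f"{vid}_VL", sequence="".join(vl), role=ChainRole.LIGHT),
            )
        )
    return variants, mutation_table(variants)


def _mutate(rng: np.random.Generator, aa: str) -> str:
    choices = [c for c in STANDARD_AA if c != aa]
    return choices[rng.integers(0, len(choices))]


# --- PEG-precipitation panels ---------------------------------------------

@dataclass(frozen=True)
class PEGPanelVariant:
    """Generating parameters of one synthetic PEG series."""

    variant_id: str
    peg_half: float
    s: float = 2.0
    a: float = 1.0
    b: float = 0.02
    noise_sd: float = 0.02
    replicates: int = 3
    c0: float = 1.0   # mg/mL


def generate_peg_series(
    variant: PEGPanelVariant,
    x_grid: np.ndarray | None = None,
    seed: int = 0,
) -> PEGSeries:
    """Simulate one PEG-precipitation series from the sigmoid model.

    Replicate measurements are the model curve plus i.i.d. Gaussian noise
    (sd `noise_sd`, in fractional-solubility units), truncated at zero.
    Poorly soluble variants (midpoint < 2.5% PEG) default to a finer
    0-8% grid, the others to 0-16% in 1% steps, emulating how assay
    ranges are chosen in practice.
    """
    if variant.noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    if variant.s <= 0:
        raise ValueError("slope s must be > 0")
    rng = np.random.default_rng(seed)
    if x_grid is None:
        x_grid = (
            np.linspace(0.0, 8.0, 17)
            if variant.peg_half < 2.5
            else np.arange(0.0, 17.0)
        )
    rows = []
    for x in x_grid:
        f = sigmoid(x, variant.a, variant.b, variant.s, variant.peg_half)
        for rep in range(variant.replicates):
            y = variant.c0 * f + variant.c0 * rng.normal(0.0, variant.noise_sd)
            rows.append((x, max(y, 0.0), rep))
    return PEGSeries(
        variant_id=variant.variant_id, points=np.array(rows), c0=variant.c0
    )


def generate_peg_panel(
    variants: list[PEGPanelVariant],
    x_grid: np.ndarray | None = None,
    seed: int = 0,
) -> list[PEGSeries]:
    """Simulate a panel of PEG series, one per variant spec.

    Each variant gets an independent noise stream derived from `seed` and
    its position in the list, so the panel is reproducible as a whole.
    """
    return [
        generate_peg_series(var, x_grid=x_grid, seed=seed + k)
        for k, var in enumerate(variants)
    ]


def default_peg_panel(seed: int = 0, noise_sd: float = 0.02) -> list[PEGSeries]:
    """Nine-variant synthetic panel with the reference panel's measured
    PEG_half values as generating midpoints."""
    from .screening import load_reference_panel

    ref = load_reference_panel()
    variants = [
        PEGPanelVariant(
            variant_id=str(vid), peg_half=float(row["peg_half"]), noise_sd=noise_sd
        )
        for vid, row in ref.iterrows()
    ]
    return generate_peg_panel(variants, seed=seed)


# --- Toy structures --------------------------------------------------------

@dataclass(frozen=True)
class ToyStructureSpec:
    """Coarse-grained synthetic structure.

    kinds:
      * ``helix``  — ideal alpha-helix CA trace (rise 1.5 A, 100 deg per
        residue, radius 2.3 A) with CB atoms pointing radially outward;
        every residue solvent-exposed.
      * ``sheet``  — extended-strand zigzag CA trace (3.5 A rise).
      * ``globule`` — CA atoms on a cubic lattice (3.8 A spacing) filling
        a ball; positions listed in `bury` occupy the innermost lattice
        sites, everything else is ordered outside-in, so designated
        residues are occluded by their neighbours.

    `jitter` adds Gaussian coordinate noise (A) drawn with `seed`;
    jitter = 0 gives fully deterministic coordinates.
    """

    sequence: str
    kind: str = "helix"
    bury: tuple = ()
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("helix", "sheet", "globule"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        n = len(self.sequence)
        if any(not 0 <= p < n for p in self.bury):
            raise ValueError("bury positions out of sequence range")


def _helix_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(n) * np.deg2rad(100.0)
    ca = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)])
    cb = np.column_stack([3.8 * np.cos(t), 3.8 * np.sin(t), 1.5 * np.arange(n)])
    return ca, cb


def _sheet_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    x = 3.5 * np.arange(n)
    y = np.where(np.arange(n) % 2 == 0, 0.6, -0.6)
    ca = np.column_stack([x, y, np.zeros(n)])
    cb = np.column_stack([x, y + np.where(np.arange(n) % 2 == 0, 1.5, -1.5), np.zeros(n)])
    return ca, cb


def _globule_coords(n: int, bury: tuple) -> np.ndarray:
    # cubic lattice sites sorted by distance from the origin
    radius = int(np.ceil((n / 4.0) ** (1 / 3))) + 2
    axis = np.arange(-radius, radius + 1)
    grid = np.array(np.meshgrid(axis, axis, axis)).reshape(3, -1).T.astype(float)
    order = np.argsort(np.linalg.norm(grid, axis=1), kind="stable")
    sites = grid[order][:n] * 3.8
    # innermost sites go to buried positions, the rest outside-in
    coords = np.empty((n, 3))
    buried = list(bury)
    others = [i for i in range(n) if i not in set(buried)]
    for rank, pos in enumerate(buried + others):
        coords[pos] = sites[rank]
    return coords


def generate_toy_structure(spec: ToyStructureSpec) -> StructureModel:
    """Build a deterministic coarse-grained StructureModel from `spec`."""
    n = len(spec.sequence)
    if spec.kind == "helix":
        ca, cb = _helix_coords(n)
    elif spec.kind == "sheet":
        ca, cb = _sheet_coords(n)
    else:
        ca, cb = _globule_coords(n, spec.bury), None

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        ca = ca + rng.normal(0.0, spec.jitter, ca.shape)
        if cb is not None:
            cb = cb + rng.normal(0.0, spec.jitter, cb.shape)

    total = sum(
        1 if (cb is None or aa == "G") else 2 for aa in spec.sequence
    )
    arr = struc.AtomArray(total)
    idx = 0
    for i, aa in enumerate(spec.sequence):
        names = ["CA"] if (cb is None or aa == "G") else ["CA", "CB"]
        for name in names:
            arr.chain_id[idx] = "A"
            arr.res_id[idx] = i + 1
            arr.res_name[idx] = _ONE_TO_THREE[aa]
            arr.atom_name[idx] = name
            arr.element[idx] = "C"
            arr.hetero[idx] = False
            arr.coord[idx] = ca[i] if name == "CA" else cb[i]
            idx += 1
    return StructureModel(atoms=arr)
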
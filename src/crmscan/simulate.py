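"""Synthetic benchmark generator: PWM libraries, orthologous promoter sets
with planted regulatory modules, negative-control sets, and toy proteomes —
all with machine-readable ground truth.

The generator emulates the inputs of a cross-species promoter analysis: for
each of ``k`` species a 5000 bp TSS-anchored region (4500 bp upstream, 500 bp
downstream) of i.i.d. background with vertebrate-like GC content, into which
one degenerate instance of each "true" TF family (NEUR, HNF1, HNF6, BRNF,
PDX1, LEFF by default) is planted inside a single window of bounded span at a
per-species variable distance from the TSS and in variable order.  Decoy
family instances are scattered outside the window and are deliberately absent
from at least one species, so the cross-species common-family filter has real
work to do.  Every plant is recorded in a JSON/BED ground-truth sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .pwm import ALPHABET, PWM, PWMLibrary, encode_sequence, reverse_complement
from .regions import RegulatoryRegion

TRUE_FAMILY_NAMES = ("NEUR", "HNF1", "HNF6", "BRNF", "PDX1", "LEFF")
DEFAULT_GC = 0.41
REGION_UPSTREAM = 4500
REGION_DOWNSTREAM = 500
REGION_LENGTH = REGION_UPSTREAM + REGION_DOWNSTREAM

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_PLACEMENT_ATTEMPTS = 10_000


class GenerationError(RuntimeError):
    """Raised when a valid placement cannot be sampled."""


# ---------------------------------------------------------------------------
# PWM library generation


def _family_names(n_true: int, n_decoy: int) -> tuple[list[str], list[str]]:
    true = list(TRUE_FAMILY_NAMES[:n_true])
    true += [f"TF{i:02d}" for i in range(len(true) + 1, n_true + 1)]
    decoys = [f"DEC{i}" for i in range(1, n_decoy + 1)]
    return true, decoys


def build_pwm_library(
    seed: int,
    n_true_families: int = 6,
    n_decoy_families: int = 4,
    motif_length_range: tuple[int, int] = (11, 14),
    matrices_per_family: int = 1,
    dominant_count: int = 17,
    total_count: int = 20,
    n_degenerate: int = 1,
) -> PWMLibrary:
    """Generate a named PWM library with true and decoy families.

    Each matrix gets a random consensus; every position holds
    ``dominant_count`` counts on the consensus base and the remainder spread
    over the other bases, except ``n_degenerate`` uniform (uninformative)
    positions.  With defaults this yields sharply informative vertebrate-like
    matrices whose 4 bp core is well defined.
    """
    lo, hi = motif_length_range
    if lo < 6:
        raise ValueError("motif lengths must be >= 6")
    if lo > hi:
        raise ValueError("motif_length_range must be (min, max) with min <= max")
    if n_true_families < 1:
        raise ValueError("need at least one true family")
    if n_decoy_families < 0 or matrices_per_family < 1:
        raise ValueError("bad family/matrix counts")
    if not 0 < dominant_count <= total_count:
        raise ValueError("dominant_count must be in (0, total_count]")

    rng = np.random.default_rng(seed)
    true, decoys = _family_names(n_true_families, n_decoy_families)
    rest = (total_count - dominant_count) // 3
    matrices: list[PWM] = []
    for family in true + decoys:
        for j in range(1, matrices_per_family + 1):
            L = int(rng.integers(lo, hi + 1))
            consensus = rng.integers(0, 4, size=L)
            counts = np.full((L, 4), rest, dtype=int)
            counts[np.arange(L), consensus] = total_count - 3 * rest
            # a few uninformative positions, never enough to erode the core
            n_deg = min(n_degenerate, max(0, L - 4))
            if n_deg:
                deg = rng.choice(L, size=n_deg, replace=False)
                counts[deg] = total_count // 4
            matrices.append(PWM(f"{family}_{j}", family, counts))
    return PWMLibrary(matrices)


# ---------------------------------------------------------------------------
# Planted promoter sets


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of a planted-module simulation.

    ``distance_range`` gives the gap (bp) between the module window's
    TSS-proximal edge and the TSS: the window occupies region coordinates
    ``[upstream - d - window_span, upstream - d)`` for a per-species draw
    ``d``.
    """

    families: tuple[str, ...] = TRUE_FAMILY_NAMES
    window_span: int = 800
    distance_range: tuple[int, int] = (1000, 3000)
    per_site_substitutions: int = 1
    order_shuffle: bool = True
    species_count: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species_count < 1:
            raise ValueError("species_count must be >= 1")
        if not self.families:
            raise ValueError("families must be non-empty")
        if self.window_span < 1:
            raise ValueError("window_span must be positive")
        dmin, dmax = self.distance_range
        if not (0 <= dmin <= dmax <= REGION_UPSTREAM - self.window_span):
            raise ValueError(
                f"distance_range must lie within [0, {REGION_UPSTREAM - self.window_span}]"
            )
        if self.per_site_substitutions < 0:
            raise ValueError("per_site_substitutions must be >= 0")


@dataclass(frozen=True)
class PlantedSite:
    """One planted motif instance, in region coordinates (0-based, half-open)."""

    species: str
    family: str
    matrix: str
    start: int
    width: int
    strand: str
    position_rel_tss: int
    site_seq: str  # the region-strand slice region[start:start+width]

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated promoter set."""

    sites: list[PlantedSite]
    windows: dict[str, tuple[int, int]]  # species -> planted window (region coords)
    negative: bool
    mode: str  # "positive" | "no_anchor" | "scattered"
    seed: int
    params: dict

    def sites_for(self, species: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.species == species]

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s.species, None)
        return list(seen)

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "negative": self.negative,
            "mode": self.mode,
            "seed": self.seed,
            "params": self.params,
            "windows": {sp: list(w) for sp, w in self.windows.items()},
            "sites": [asdict(s) for s in self.sites],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            sites=[PlantedSite(**s) for s in d["sites"]],
            windows={sp: (int(w[0]), int(w[1])) for sp, w in d["windows"].items()},
            negative=bool(d["negative"]),
            mode=d["mode"],
            seed=int(d["seed"]),
            params=d["params"],
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SyntheticTruth":
        return cls.from_json_dict(json.loads(Path(path).read_text()))

    def to_bed6(self) -> str:
        """Planted sites as BED6 in region-relative coordinates."""
        lines = [
            f"{s.species}\t{s.start}\t{s.end}\t{s.family}:{s.matrix}\t0\t{s.strand}"
            for s in self.sites
        ]
        return "\n".join(lines) + ("\n" if lines else "")


def _sample_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


def _mutate_instance(pwm: PWM, n_subs: int, rng: np.random.Generator) -> str:
    """Consensus instance with ``n_subs`` random substitutions, applied at
    non-core positions first so core similarity stays maximal."""
    seq = list(pwm.consensus)
    core = set(int(i) for i in pwm.core)
    noncore = [i for i in range(len(seq)) if i not in core]
    order = list(rng.permutation(noncore)) + list(rng.permutation(sorted(core)))
    for pos in order[: min(n_subs, len(seq))]:
        alternatives = [b for b in ALPHABET if b != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(3))]
    return "".join(seq)


def _place_nonoverlapping(
    rng: np.random.Generator,
    widths: Sequence[int],
    lo: int,
    hi: int,
    taken: list[tuple[int, int]],
    families: Sequence[str],
) -> list[int]:
    """Sample non-overlapping start positions in [lo, hi) by rejection."""
    placed: list[int] = []
    intervals = list(taken)
    for w, fam in zip(widths, families):
        upper = hi - w
        if upper < lo:
            raise GenerationError(f"window too small for family {fam} (width {w})")
        for _ in range(_PLACEMENT_ATTEMPTS):
            s = int(rng.integers(lo, upper + 1))
            if all(s + w <= a or s >= b for a, b in intervals):
                intervals.append((s, s + w))
                placed.append(s)
                break
        else:
            raise GenerationError(
                f"could not place non-overlapping sites; colliding families: "
                f"{', '.join(families)}"
            )
    return placed


def _embed(site: str, strand: str, start: int, seq: np.ndarray) -> str:
    oriented = site if strand == "+" else reverse_complement(site)
    seq[start : start + len(site)] = encode_sequence(oriented)
    return oriented


def _decode(seq: np.ndarray) -> str:
    return "".join(ALPHABET[int(i)] for i in seq)


def _decoy_presence(
    rng: np.random.Generator, decoy_families: Sequence[str], n_species: int, p: float
) -> dict[str, np.ndarray]:
    """Per-species presence mask per decoy family; each decoy is forced absent
    from at least one species so it can never be a common family."""
    masks = {}
    for fam in decoy_families:
        mask = rng.random(n_species) < p
        if mask.all():
            mask[int(rng.integers(n_species))] = False
        masks[fam] = mask
    return masks


def _species_names(n: int) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(n)]


def _make_region(species: str, seq: str, gene_id: str, paralog: str) -> RegulatoryRegion:
    return RegulatoryRegion(
        gene_id=gene_id,
        species=species,
        paralog=paralog,
        sequence=seq,
        contig=f"synthetic_{species}",
        start=0,
        end=len(seq),
        strand="+",
        tss_offset=REGION_UPSTREAM,
    )


def _pick_matrix(library: PWMLibrary, family: str, rng: np.random.Generator) -> PWM:
    mats = library.by_family(family)
    if not mats:
        raise ValueError(f"library has no matrix for family {family!r}")
    return mats[int(rng.integers(len(mats)))]


def simulate_ortholog_promoters(
    library: PWMLibrary,
    spec: PlantSpec,
    gc: float = DEFAULT_GC,
    decoy_presence: float = 0.6,
    gene_id: str = "simgene",
    paralog: str = "a",
    excluded_families: Sequence[str] = (),
) -> tuple[list[RegulatoryRegion], SyntheticTruth]:
    """Simulate one orthologous promoter set with a planted module.

    Every species receives one degenerate instance of each family in
    ``spec.families``, all inside a single window of span
    ``<= spec.window_span`` whose distance from the TSS is drawn per species
    from ``spec.distance_range``; decoy-family instances are scattered
    uniformly outside the window.
    """
    missing = [f for f in spec.families if not library.by_family(f)]
    if missing:
        raise ValueError(f"library lacks families: {', '.join(missing)}")
    rng = np.random.default_rng(spec.seed)
    species = _species_names(spec.species_count)
    decoys = [
        f
        for f in library.families
        if f not in spec.families and f not in excluded_families
    ]
    presence = _decoy_presence(rng, decoys, spec.species_count, decoy_presence)

    regions: list[RegulatoryRegion] = []
    sites: list[PlantedSite] = []
    windows: dict[str, tuple[int, int]] = {}
    for si, sp in enumerate(species):
        seq = _sample_background(rng, REGION_LENGTH, gc)
        d = int(rng.integers(spec.distance_range[0], spec.distance_range[1] + 1))
        w_end = REGION_UPSTREAM - d
        w_start = w_end - spec.window_span
        windows[sp] = (w_start, w_end)

        fams = list(spec.families)
        if spec.order_shuffle:
            fams = [fams[int(i)] for i in rng.permutation(len(fams))]
        mats = [_pick_matrix(library, f, rng) for f in fams]
        instances = [_mutate_instance(m, spec.per_site_substitutions, rng) for m in mats]
        starts = _place_nonoverlapping(
            rng, [len(x) for x in instances], w_start, w_end, [], fams
        )
        placed = [(s, s + len(x)) for s, x in zip(starts, instances)]
        for fam, mat, inst, s in zip(fams, mats, instances, starts):
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = _embed(inst, strand, s, seq)
            sites.append(
                PlantedSite(
                    species=sp,
                    family=fam,
                    matrix=mat.name,
                    start=s,
                    width=len(inst),
                    strand=strand,
                    position_rel_tss=s - REGION_UPSTREAM,
                    site_seq=oriented,
                )
            )

        # decoys: uniform over the region, outside the module window
        for fam in decoys:
            if not presence[fam][si]:
                continue
            mat = _pick_matrix(library, fam, rng)
            inst = _mutate_instance(mat, spec.per_site_substitutions, rng)
            w = len(inst)
            for _ in range(_PLACEMENT_ATTEMPTS):
                s = int(rng.integers(0, REGION_LENGTH - w + 1))
                outside = s + w <= w_start or s >= w_end
                if outside and all(s + w <= a or s >= b for a, b in placed):
                    break
            else:
                raise GenerationError(f"could not place decoy family {fam}")
            placed.append((s, s + w))
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = _embed(inst, strand, s, seq)
            sites.append(
                PlantedSite(
                    species=sp,
                    family=fam,
                    matrix=mat.name,
                    start=s,
                    width=w,
                    strand=strand,
                    position_rel_tss=s - REGION_UPSTREAM,
                    site_seq=oriented,
                )
            )
        regions.append(_make_region(sp, _decode(seq), gene_id, paralog))

    truth = SyntheticTruth(
        sites=sites,
        windows=windows,
        negative=False,
        mode="positive",
        seed=spec.seed,
        params={
            "families": list(spec.families),
            "window_span": spec.window_span,
            "distance_range": list(spec.distance_range),
            "per_site_substitutions": spec.per_site_substitutions,
            "order_shuffle": spec.order_shuffle,
            "species_count": spec.species_count,
            "gc": gc,
        },
    )
    return regions, truth


def simulate_control_promoters(
    library: PWMLibrary,
    spec: PlantSpec,
    mode: str,
    gc: float = DEFAULT_GC,
    decoy_presence: float = 0.6,
    scatter_gap: int = 1000,
    gene_id: str = "control",
    paralog: str = "a",
) -> tuple[list[RegulatoryRegion], SyntheticTruth]:
    """Simulate a negative-control promoter set.

    ``no_anchor`` plants the non-anchor families co-localized exactly like the
    positive sets but omits the anchor (first) family.  ``scattered`` plants
    all families with the anchor site more than ``scatter_gap`` bp away from
    every other family's site in every species, so no anchored window of span
    <= ``scatter_gap`` can co-localize the module.
    """
    if mode not in ("no_anchor", "scattered"):
        raise ValueError(f"unknown control mode {mode!r}")
    if mode == "no_anchor":
        sub = PlantSpec(
            families=spec.families[1:],
            window_span=spec.window_span,
            distance_range=spec.distance_range,
            per_site_substitutions=spec.per_site_substitutions,
            order_shuffle=spec.order_shuffle,
            species_count=spec.species_count,
            seed=spec.seed,
        )
        regions, truth = simulate_ortholog_promoters(
            library, sub, gc=gc, decoy_presence=decoy_presence,
            gene_id=gene_id, paralog=paralog,
            excluded_families=(spec.families[0],),  # truly no anchor sites
        )
        truth.negative = True
        truth.mode = "no_anchor"
        truth.windows = {}
        truth.params["families"] = list(spec.families)
        truth.params["anchor_family"] = spec.families[0]
        return regions, truth

    # scattered
    missing = [f for f in spec.families if not library.by_family(f)]
    if missing:
        raise ValueError(f"library lacks families: {', '.join(missing)}")
    rng = np.random.default_rng(spec.seed)
    species = _species_names(spec.species_count)
    anchor_family, others = spec.families[0], list(spec.families[1:])

    regions: list[RegulatoryRegion] = []
    sites: list[PlantedSite] = []
    for sp in species:
        seq = _sample_background(rng, REGION_LENGTH, gc)
        a_mat = _pick_matrix(library, anchor_family, rng)
        a_inst = _mutate_instance(a_mat, spec.per_site_substitutions, rng)
        a_start = int(rng.integers(0, 200))
        zone_lo = a_start + len(a_inst) + scatter_gap + 1
        zone_hi = REGION_UPSTREAM
        mirror = rng.random() < 0.5  # put the anchor near the TSS instead
        placements: list[tuple[str, PWM, str, int]] = []
        o_mats = [_pick_matrix(library, f, rng) for f in others]
        o_insts = [_mutate_instance(m, spec.per_site_substitutions, rng) for m in o_mats]
        if others:
            stride = (zone_hi - zone_lo) // len(others)
            if stride < max(len(x) for x in o_insts) + 1:
                raise GenerationError(
                    "scattered control cannot fit families: " + ", ".join(spec.families)
                )
            for j, (fam, mat, inst) in enumerate(zip(others, o_mats, o_insts)):
                jitter = int(rng.integers(0, max(1, stride - len(inst))))
                placements.append((fam, mat, inst, zone_lo + j * stride + jitter))
        placements.append((anchor_family, a_mat, a_inst, a_start))
        if mirror:
            placements = [
                (fam, mat, inst, REGION_UPSTREAM - (s + len(inst)))
                for fam, mat, inst, s in placements
            ]
        for fam, mat, inst, s in placements:
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = _embed(inst, strand, s, seq)
            sites.append(
                PlantedSite(
                    species=sp,
                    family=fam,
                    matrix=mat.name,
                    start=s,
                    width=len(inst),
                    strand=strand,
                    position_rel_tss=s - REGION_UPSTREAM,
                    site_seq=oriented,
                )
            )
        regions.append(_make_region(sp, _decode(seq), gene_id, paralog))

    truth = SyntheticTruth(
        sites=sites,
        windows={},
        negative=True,
        mode="scattered",
        seed=spec.seed,
        params={
            "families": list(spec.families),
            "anchor_family": anchor_family,
            "scatter_gap": scatter_gap,
            "species_count": spec.species_count,
            "gc": gc,
        },
    )
    return regions, truth


# ---------------------------------------------------------------------------
# Toy proteomes


@dataclass
class OrthologTruth:
    """Planted ortholog structure of a toy proteome set."""

    ortholog_ids: dict[str, dict[str, str]]  # family -> species -> copy-1 gene id
    paralog_ids: dict[str, dict[str, str]]  # duplicated family -> species -> copy-2 id
    species: list[str]

    def pairs(self, species_a: str, species_b: str) -> list[tuple[str, str]]:
        return sorted(
            (m[species_a], m[species_b])
            for m in self.ortholog_ids.values()
            if species_a in m and species_b in m
        )

    def to_json_dict(self) -> dict:
        return {
            "ortholog_ids": self.ortholog_ids,
            "paralog_ids": self.paralog_ids,
            "species": self.species,
        }


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        alternatives = [a for a in AMINO_ACIDS if a != arr[i]]
        arr[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(arr)


def simulate_proteomes(
    n_families: int = 20,
    species: int = 2,
    duplication_fraction: float = 0.2,
    divergence: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], OrthologTruth]:
    """Toy proteomes with known ortholog/paralog structure (star phylogeny).

    Each species carries one copy of every gene family diverged from a common
    ancestor at ``divergence`` substitutions per site.  A
    ``duplication_fraction`` of families additionally carry an in-paralog
    diverged at three times that rate (capped at 0.45), so the copy-1 genes
    are unambiguously the closer orthologs.
    """
    if not 0 <= duplication_fraction <= 1:
        raise ValueError("duplication_fraction must be in [0, 1]")
    if not 0 <= divergence < 0.5:
        raise ValueError("divergence must be in [0, 0.5)")
    if n_families < 1 or species < 1:
        raise ValueError("need >= 1 family and >= 1 species")
    rng = np.random.default_rng(seed)
    sp_names = [f"sp{i + 1}" for i in range(species)]
    lengths = rng.integers(150, 451, size=n_families)
    ancestors = [
        "".join(AMINO_ACIDS[int(i)] for i in rng.integers(0, 20, size=int(L)))
        for L in lengths
    ]
    n_dup = int(round(duplication_fraction * n_families))
    dup_idx = set(int(i) for i in rng.choice(n_families, size=n_dup, replace=False))
    dup_rate = min(0.45, 3.0 * divergence)

    proteomes: dict[str, dict[str, str]] = {sp: {} for sp in sp_names}
    ortholog_ids: dict[str, dict[str, str]] = {}
    paralog_ids: dict[str, dict[str, str]] = {}
    for f, anc in enumerate(ancestors):
        fam = f"fam{f:03d}"
        ortholog_ids[fam] = {}
        if f in dup_idx:
            paralog_ids[fam] = {}
        for sp in sp_names:
            gid = f"{sp}.g{f:03d}"
            proteomes[sp][gid] = _mutate_protein(anc, divergence, rng)
            ortholog_ids[fam][sp] = gid
            if f in dup_idx:
                pid = f"{sp}.g{f:03d}b"
                proteomes[sp][pid] = _mutate_protein(anc, dup_rate, rng)
                paralog_ids[fam][sp] = pid
    truth = OrthologTruth(ortholog_ids=ortholog_ids, paralog_ids=paralog_ids, species=sp_names)
    return proteomes, truth


def write_proteome_fasta(proteome: Mapping[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for gid, seq in proteome.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
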
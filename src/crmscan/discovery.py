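"""Conserved anchored-module discovery across orthologous promoters.

The filtering cascade mirrors classical phylogenetic footprinting of
composite cis-regulatory elements:

1. keep only TF families with at least one retained binding site in every
   orthologous region (*common* families);
2. rank the anchor family's sites (NEUR by default) by similarity and treat
   the best ones as window anchors;
3. in every species, search windows of bounded span (default <= 1000 bp)
   that contain an anchor site;
4. the reported module is the largest common family set that some anchored
   window co-localizes in *every* species; paralogs are then compared by
   module presence/absence.

No positional homology is assumed: per-species windows may sit at different
distances from the TSS and order sites differently.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .pwm import TFBSHit, DEFAULT_TSS_OFFSET

logger = logging.getLogger("crmscan.discovery")

DEFAULT_ANCHOR_FAMILY = "NEUR"
DEFAULT_MAX_SPAN = 1000
DEFAULT_MIN_FAMILIES = 2
DEFAULT_TOP_K_ANCHORS = 3


def _key(hit: TFBSHit, matrix_level: bool) -> str:
    return hit.matrix if matrix_level else hit.family


def common_families(
    hits_by_species: Mapping[str, Sequence[TFBSHit]],
    matrix_level: bool = False,
) -> set[str]:
    """Families (or matrices, with ``matrix_level``) with >= 1 retained hit in
    every species' region.  A species with no hits contributes the empty set,
    so the result may be empty."""
    if len(hits_by_species) < 2:
        warnings.warn("common_families called with fewer than 2 species", stacklevel=2)
    sets = [
        {_key(h, matrix_level) for h in hits}
        for hits in hits_by_species.values()
    ]
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def select_anchors(
    hits: Sequence[TFBSHit],
    anchor_family: str = DEFAULT_ANCHOR_FAMILY,
    top_k: int = DEFAULT_TOP_K_ANCHORS,
) -> list[TFBSHit]:
    """Anchor-family hits ranked by matrix similarity, then core similarity,
    then proximity to the TSS; the best ``top_k`` are returned with all hits
    tying the k-th rank key kept."""
    anchors = [h for h in hits if h.family == anchor_family]
    keyed = sorted(
        anchors,
        key=lambda h: (
            -h.matrix_similarity,
            -h.core_similarity,
            abs(h.position_rel_tss),
            h.start,
        ),
    )
    if len(keyed) <= top_k:
        return keyed
    cut = keyed[top_k - 1]
    cut_key = (cut.matrix_similarity, cut.core_similarity, abs(cut.position_rel_tss))
    out = keyed[:top_k]
    for h in keyed[top_k:]:
        if (h.matrix_similarity, h.core_similarity, abs(h.position_rel_tss)) == cut_key:
            out.append(h)
        else:
            break
    return out


@dataclass
class ModuleWindow:
    """The module's realization in one species."""

    species: str
    start: int  # region coordinates, 0-based half-open
    end: int
    anchor: TFBSHit
    members: list[TFBSHit]
    tss_offset: int = DEFAULT_TSS_OFFSET

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def start_rel_tss(self) -> int:
        return self.start - self.tss_offset

    @property
    def end_rel_tss(self) -> int:
        return self.end - self.tss_offset

    @property
    def distance_from_tss(self) -> int:
        """Distance (bp) of the window's TSS-proximal edge from the TSS."""
        return max(0, self.tss_offset - self.end)

    @property
    def families(self) -> set[str]:
        return {h.family for h in self.members}

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "start": self.start,
            "end": self.end,
            "start_rel_tss": self.start_rel_tss,
            "end_rel_tss": self.end_rel_tss,
            "span": self.span,
            "distance_from_tss": self.distance_from_tss,
            "anchor": vars(self.anchor) | {"end": self.anchor.end},
            "members": [vars(h) | {"end": h.end} for h in self.members],
        }


@dataclass
class RegulatoryModule:
    """A conserved anchored TFBS module across orthologous regions."""

    gene_id: str
    families: tuple[str, ...]
    anchor_family: str
    windows: dict[str, ModuleWindow]
    max_span: int = DEFAULT_MAX_SPAN

    @property
    def n_families(self) -> int:
        return len(self.families)

    def to_dict(self) -> dict:
        return {
            "found": True,
            "gene_id": self.gene_id,
            "families": sorted(self.families),
            "anchor_family": self.anchor_family,
            "max_span": self.max_span,
            "windows": {sp: w.to_dict() for sp, w in sorted(self.windows.items())},
        }


def write_module_json(module: RegulatoryModule | None, path: Union[str, Path]) -> None:
    payload = module.to_dict() if module is not None else {"found": False}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _candidate_windows(
    hits: Sequence[TFBSHit],
    anchors: Sequence[TFBSHit],
    candidate_families: set[str],
    max_span: int,
):
    """Enumerate tight anchored windows.

    Yields ``(family_frozenset, span, start, end, anchor, members)`` for every
    distinct member set obtainable as the hits of candidate families falling
    inside an interval bounded by hit coordinates, of span <= max_span and
    containing an anchor.  Member sets are deduplicated by their tight hull.
    """
    cand = [h for h in hits if h.family in candidate_families]
    anchor_set = {(a.start, a.matrix, a.strand) for a in anchors}
    seen: set[tuple[int, int]] = set()
    starts = sorted({h.start for h in cand})
    ends = sorted({h.end for h in cand})
    for s in starts:
        for e in ends:
            if e <= s or e - s > max_span:
                continue
            members = [h for h in cand if h.start >= s and h.end <= e]
            if not members:
                continue
            hull_s = min(h.start for h in members)
            hull_e = max(h.end for h in members)
            if (hull_s, hull_e) in seen:
                continue
            seen.add((hull_s, hull_e))
            anchor_members = [
                h for h in members if (h.start, h.matrix, h.strand) in anchor_set
            ]
            if not anchor_members:
                continue
            fams = frozenset(h.family for h in members)
            yield fams, hull_e - hull_s, hull_s, hull_e, anchor_members[0], members


def find_module_window(
    hits: Sequence[TFBSHit],
    anchor: TFBSHit,
    candidate_families: set[str],
    max_span: int = DEFAULT_MAX_SPAN,
    species: str = "",
    tss_offset: int = DEFAULT_TSS_OFFSET,
) -> ModuleWindow | None:
    """Best window of span <= ``max_span`` containing the given anchor hit:
    maximal number of distinct candidate families covered, then minimal span,
    then leftmost."""
    if anchor not in hits:
        raise ValueError("anchor must be one of the supplied hits")
    fams = candidate_families | {anchor.family}
    best = None
    for fset, span, s, e, a, members in _candidate_windows(hits, [anchor], fams, max_span):
        key = (-len(fset), span, s)
        if best is None or key < best[0]:
            best = (key, s, e, members)
    if best is None:
        return None
    _, s, e, members = best
    return ModuleWindow(
        species=species, start=s, end=e, anchor=anchor, members=members,
        tss_offset=tss_offset,
    )


def detect_conserved_module(
    hits_by_species: Mapping[str, Sequence[TFBSHit]],
    anchor_family: str = DEFAULT_ANCHOR_FAMILY,
    max_span: int = DEFAULT_MAX_SPAN,
    min_families: int = DEFAULT_MIN_FAMILIES,
    top_k_anchors: int = DEFAULT_TOP_K_ANCHORS,
    matrix_level: bool = False,
    min_species_fraction: float = 1.0,
    gene_id: str = "",
    tss_offset: int = DEFAULT_TSS_OFFSET,
) -> RegulatoryModule | None:
    """Call the conserved module, if any.

    The module family set is the largest set ``S`` (anchor included, drawn
    from the cross-species common families) such that in every species some
    anchored window of span <= ``max_span`` covers all of ``S``; per-species
    windows are then chosen independently (minimal span, then leftmost).
    Returns None when a species lacks an anchor site, when fewer than
    ``min_families`` families co-localize, or when the anchor family is not
    common.  ``min_species_fraction < 1`` relaxes "every species" to a
    fraction (the module then reports windows only for covered species).
    """
    if not hits_by_species:
        return None
    n_species = len(hits_by_species)
    needed = max(1, int(-(-min_species_fraction * n_species // 1)))  # ceil

    cf = common_families(hits_by_species, matrix_level=False) if min_species_fraction >= 1.0 else {
        f
        for hits in hits_by_species.values()
        for f in {h.family for h in hits}
    }
    if anchor_family not in cf:
        logger.info("%s: anchor family %s not common to all species", gene_id, anchor_family)
        if min_species_fraction >= 1.0:
            return None

    per_species: dict[str, list] = {}
    for sp, hits in hits_by_species.items():
        anchors = select_anchors(hits, anchor_family, top_k=top_k_anchors)
        if not anchors:
            logger.info("%s: species %s has no %s anchor", gene_id, sp, anchor_family)
            if min_species_fraction >= 1.0:
                return None
            per_species[sp] = []
            continue
        per_species[sp] = list(
            _candidate_windows(hits, anchors, set(cf), max_span)
        )

    # prefilter: a family is viable only if co-coverable with the anchor in
    # enough species
    def covered_in(sp: str, S: frozenset) -> bool:
        return any(S <= fset for fset, *_ in per_species[sp])

    viable = set()
    for f in cf:
        S = frozenset({anchor_family, f})
        if sum(covered_in(sp, S) for sp in per_species) >= needed:
            viable.add(f)
    viable.discard(anchor_family)
    viable = sorted(viable)

    best_set: frozenset | None = None
    for size in range(len(viable), -1, -1):
        candidates = []
        for combo in combinations(viable, size):
            S = frozenset(combo) | {anchor_family}
            n_cov = sum(covered_in(sp, S) for sp in per_species)
            if n_cov >= needed:
                candidates.append(tuple(sorted(S)))
        if candidates:
            best_set = frozenset(min(candidates))
            break
    if best_set is None or len(best_set) < min_families:
        return None

    windows: dict[str, ModuleWindow] = {}
    for sp in hits_by_species:
        options = [
            (span, s, e, a, members)
            for fset, span, s, e, a, members in per_species[sp]
            if best_set <= fset
        ]
        if not options:
            continue  # only possible when min_species_fraction < 1
        span, s, e, a, members = min(options, key=lambda o: (o[0], o[1]))
        members_S = [h for h in members if h.family in best_set]
        hull_s = min(h.start for h in members_S)
        hull_e = max(h.end for h in members_S)
        windows[sp] = ModuleWindow(
            species=sp, start=hull_s, end=hull_e, anchor=a,
            members=sorted(members_S), tss_offset=tss_offset,
        )
    if len(windows) < needed:
        return None
    return RegulatoryModule(
        gene_id=gene_id,
        families=tuple(sorted(best_set)),
        anchor_family=anchor_family,
        windows=windows,
        max_span=max_span,
    )


def compare_paralogs(
    species: Sequence[str],
    module_a: RegulatoryModule | None,
    module_b: RegulatoryModule | None,
    labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Per-species module presence/absence table for two paralogs."""
    universe = set(species)
    for mod, label in ((module_a, labels[0]), (module_b, labels[1])):
        if mod is not None and not set(mod.windows) <= universe:
            raise ValueError(
                f"species set mismatch for paralog {label}: "
                f"{sorted(set(mod.windows) - universe)}"
            )
    rows = {
        labels[0]: [module_a is not None and sp in module_a.windows for sp in species],
        labels[1]: [module_b is not None and sp in module_b.windows for sp in species],
    }
    return pd.DataFrame(rows, index=list(species))


def write_paralog_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, sep="\t", index_label="species")
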
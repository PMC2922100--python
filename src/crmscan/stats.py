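"""Clustering statistics for module families.

For each family the observed number of binding sites inside the module
windows is compared against a Binomial null whose per-trial hit probability
is measured empirically on random background: ``background_hit_rate`` is the
retained-hit frequency per strand-specific scorable window, and the module
p-value is the upper Binomial tail over the strand-windows contained in the
per-species module windows.  This is a defined, testable clustering statistic
of this package's own design.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .discovery import RegulatoryModule
from .pwm import (
    DEFAULT_CORE_CUT,
    PWM,
    PWMLibrary,
    _EPS,
    _background_matrix_sims,
    random_background,
)


def background_hit_rate(
    pwm: PWM,
    background_gc: float = 0.41,
    length: int = 100_000,
    seed: int = 0,
    threshold: float = 0.8,
    core_cut: float = DEFAULT_CORE_CUT,
) -> float:
    """Per-strand-window probability of a retained hit on random background.

    Counts hits over both strands of a seeded i.i.d. background and divides
    by ``2 x scorable positions``.
    """
    if length < 10_000:
        raise ValueError("background length must be >= 10,000 bp")
    positions = length - len(pwm) + 1
    if positions <= 0:
        raise ValueError("no scorable positions")
    background = random_background(length, gc=background_gc, seed=seed)
    sims = _background_matrix_sims(pwm, background, core_cut)
    hits = int(np.count_nonzero(sims >= threshold - _EPS))
    return hits / (2.0 * positions)


def family_clustering_pvalue(k: int, L_eff: int, p_bg: float) -> float:
    """Upper Binomial tail ``P(X >= k)`` with ``X ~ Binomial(L_eff, p_bg)``.

    ``k = 0`` returns 1 exactly; ``k > L_eff`` is impossible under the null
    and returns 0 with a warning.
    """
    if k < 0 or L_eff < 0:
        raise ValueError("k and L_eff must be non-negative")
    if not 0 <= p_bg <= 1:
        raise ValueError("p_bg must be a probability")
    if k == 0:
        return 1.0
    if k > L_eff:
        warnings.warn(f"k={k} exceeds the number of trials L_eff={L_eff}", stacklevel=2)
        return 0.0
    return float(sps.binom.sf(k - 1, L_eff, p_bg))


def module_family_stats(
    module: RegulatoryModule,
    library: PWMLibrary,
    thresholds: Mapping[str, float],
    background_gc: float = 0.41,
    background_length: int = 100_000,
    seed: int = 0,
    core_cut: float = DEFAULT_CORE_CUT,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-family clustering statistics aggregated over species.

    For family ``f``: ``k`` = member hits across all species' windows;
    ``L_eff`` = sum over species of ``span - L + 1`` scorable positions
    (``L`` = motif length); trials = ``2 x L_eff`` strand-windows with the
    empirical per-strand-window rate ``p_bg``.  Rows sorted by p-value.
    """
    rows = []
    n_fam = len(module.families)
    for fam in module.families:
        mats = library.by_family(fam)
        if not mats:
            raise ValueError(f"library lacks family {fam!r}")
        pwm = mats[0]
        p_bg = float(
            np.mean(
                [
                    background_hit_rate(
                        m,
                        background_gc=background_gc,
                        length=background_length,
                        seed=seed,
                        threshold=thresholds.get(m.name, 0.8)
                        if isinstance(thresholds, Mapping)
                        else float(thresholds),
                        core_cut=core_cut,
                    )
                    for m in mats
                ]
            )
        )
        k = 0
        L_eff = 0
        for w in module.windows.values():
            k += sum(1 for h in w.members if h.family == fam)
            L_eff += max(0, w.span - len(pwm) + 1)
        p = family_clustering_pvalue(k, 2 * L_eff, p_bg)
        if bonferroni:
            p = min(1.0, p * n_fam)
        rows.append(
            {"family": fam, "p_value": p, "k": k, "L_eff": L_eff, "p_bg": p_bg}
        )
    df = pd.DataFrame(rows, columns=["family", "p_value", "k", "L_eff", "p_bg"])
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def write_stats_tsv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
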
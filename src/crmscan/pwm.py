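"""Position-weight-matrix scoring and strand-aware scanning.

Implements MatInspector-style similarity scoring: each matrix carries a
per-position conservation (information) vector ``Ci`` in [0, 100]; candidate
sites are scored by the information-weighted frequency of their bases relative
to the best attainable weighted frequency, so a consensus match scores exactly
1.0.  Two scores are produced per window:

* *matrix similarity* — over the full matrix length;
* *core similarity*  — over the 4 most-conserved consecutive positions
  (the "core"), used as a cheap first-pass filter (default cut-off 0.75).

Matrix-specific "optimized" thresholds are calibrated empirically: the lowest
matrix-similarity cut-off (on a 0.01 grid) at which a long random background
sequence yields no more than a target number of matches per 10 kb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

ALPHABET = "ACGT"
_BASE_TO_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_LN4 = math.log(4.0)
_INFO_SCALE = 100.0 / _LN4

#: pseudocount fraction of the row total added to scoring frequencies
DEFAULT_PSEUDOCOUNT = 1e-4
DEFAULT_CORE_LENGTH = 4
DEFAULT_CORE_CUT = 0.75
#: fallback matrix-similarity threshold when no calibration is supplied
DEFAULT_MATRIX_THRESHOLD = 0.80
#: grid searched by :func:`calibrate_optimized_threshold`
THRESHOLD_GRID = np.round(np.arange(0.50, 1.0001, 0.01), 2)
#: numeric slack for >= comparisons against cut-offs
_EPS = 1e-9

# default TSS offset inside a regulatory region (4500 bp upstream + 500 down)
DEFAULT_TSS_OFFSET = 4500


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 indices into ACGT; anything else
    (N, gaps, IUPAC ambiguity) becomes -1 and the containing windows are
    skipped during scanning."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(raw.shape, -1, dtype=np.int8)
    for base, idx in _BASE_TO_INDEX.items():
        out[raw == ord(base)] = idx
    return out


def information_vector(counts: Sequence[Sequence[float]]) -> np.ndarray:
    """Per-position conservation ``Ci = (100/ln4) * (ln4 + sum_b f_b ln f_b)``.

    Computed on the raw (pre-pseudocount) frequencies.  A row concentrated on
    a single base scores exactly 100; a uniform row scores 0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be an L x 4 array")
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every count row must have a positive total")
    freqs = counts / totals[:, None]
    plogp = np.where(freqs > 0, freqs * np.log(np.where(freqs > 0, freqs, 1.0)), 0.0)
    ci = _INFO_SCALE * (_LN4 + plogp.sum(axis=1))
    ci = np.clip(ci, 0.0, 100.0)
    # exact endpoints: Ci == 100 iff the row has a single non-zero entry
    single = (counts > 0).sum(axis=1) == 1
    ci[single] = 100.0
    ci[~single] = np.minimum(ci[~single], np.nextafter(100.0, 0.0))
    return ci


def core_positions(info: Sequence[float], core_length: int = DEFAULT_CORE_LENGTH) -> np.ndarray:
    """Indices of the ``core_length`` consecutive positions maximizing summed
    Ci; ties resolved toward the smallest start index."""
    info = np.asarray(info, dtype=float)
    if info.ndim != 1:
        raise ValueError("info must be a vector")
    if len(info) < core_length:
        raise ValueError(
            f"matrix length {len(info)} shorter than core length {core_length}"
        )
    sums = np.convolve(info, np.ones(core_length), mode="valid")
    start = int(np.flatnonzero(sums >= sums.max() - _EPS)[0])
    return np.arange(start, start + core_length)


class PWM:
    """A named position frequency matrix with derived scoring machinery.

    Parameters
    ----------
    name, family
        Matrix identifier and TF-family label (e.g. ``NEUR_1`` / ``NEUR``).
    counts
        L x 4 non-negative integer counts, columns ordered A, C, G, T.
    pseudocount
        Fraction of each row total added to every cell for the *scoring*
        frequencies (the information vector always uses raw frequencies).
    """

    def __init__(
        self,
        name: str,
        family: str,
        counts: Sequence[Sequence[int]],
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        core_length: int = DEFAULT_CORE_LENGTH,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"{name}: counts must be L x 4")
        if counts.shape[0] < 1:
            raise ValueError(f"{name}: empty matrix")
        if np.any(counts < 0):
            raise ValueError(f"{name}: negative counts")
        self.name = name
        self.family = family
        self.counts = counts
        self.pseudocount = float(pseudocount)
        self.core_length = int(core_length)

        totals = counts.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError(f"{name}: all-zero count row")
        self.freqs = (counts + pseudocount * totals[:, None]) / (
            totals[:, None] * (1.0 + 4.0 * pseudocount)
        )
        self.info = information_vector(counts)
        if not np.any(self.info > 0):
            raise ValueError(f"{name}: matrix carries no information (all Ci == 0)")
        # matrices shorter than the core length use the whole matrix as core
        self.core = core_positions(self.info, min(core_length, len(self.info)))
        self.consensus = "".join(ALPHABET[i] for i in np.argmax(self.freqs, axis=1))

        # scoring tables:  weight[i, b] = Ci * f(i, b)
        self._weights = self.info[:, None] * self.freqs
        best = self.info * self.freqs.max(axis=1)
        self._denom = float(best.sum())
        self._core_denom = float(best[self.core].sum())
        self._row_max = self.freqs.max(axis=1)

    def __len__(self) -> int:
        return self.counts.shape[0]

    def __repr__(self) -> str:
        return f"PWM({self.name!r}, family={self.family!r}, L={len(self)})"

    # -- scoring -----------------------------------------------------------

    def _scores_encoded(self, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(matrix_similarity, core_similarity) for an m x L int array of
        base indices (all >= 0)."""
        L = len(self)
        pos = np.arange(L)
        contrib = self._weights[pos[None, :], windows]
        msim = contrib.sum(axis=1) / self._denom
        csim = contrib[:, self.core].sum(axis=1) / self._core_denom
        return msim, csim

    def matrix_similarity(self, s: str) -> float:
        """Information-weighted similarity of ``s`` to the matrix, in (0, 1];
        1.0 iff ``s`` matches a consensus (argmax base at every position).
        Windows containing non-ACGT characters score 0."""
        if len(s) != len(self):
            raise ValueError(f"window length {len(s)} != matrix length {len(self)}")
        enc = encode_sequence(s)
        if np.any(enc < 0):
            return 0.0
        return float(self._scores_encoded(enc[None, :])[0][0])

    def core_similarity(self, s: str) -> float:
        """Same score restricted to the core positions."""
        if len(s) != len(self):
            raise ValueError(f"window length {len(s)} != matrix length {len(self)}")
        enc = encode_sequence(s)
        if np.any(enc < 0):
            return 0.0
        return float(self._scores_encoded(enc[None, :])[1][0])

    def is_consensus(self, s: str) -> bool:
        enc = encode_sequence(s)
        if len(s) != len(self) or np.any(enc < 0):
            return False
        return bool(
            np.all(self.freqs[np.arange(len(self)), enc] >= self._row_max - 1e-12)
        )


@dataclass(frozen=True, order=True)
class TFBSHit:
    """A retained binding-site match on a regulatory region.

    ``start`` is the region-relative 0-based offset of the leftmost base of
    the site on the forward (gene-strand) coordinate system regardless of the
    matched strand; ``position_rel_tss = start - tss_offset`` (negative =
    upstream of the TSS).
    """

    start: int
    matrix: str
    strand: str
    family: str = field(compare=False)
    width: int = field(compare=False)
    position_rel_tss: int = field(compare=False)
    core_similarity: float = field(compare=False)
    matrix_similarity: float = field(compare=False)

    @property
    def end(self) -> int:
        return self.start + self.width


class PWMLibrary:
    """An ordered collection of named PWMs grouped into families."""

    def __init__(self, matrices: Iterable[PWM]):
        self.matrices = list(matrices)
        names = [m.name for m in self.matrices]
        if len(set(names)) != len(names):
            raise ValueError("duplicate matrix names in library")
        self._by_name = {m.name: m for m in self.matrices}

    def __iter__(self) -> Iterator[PWM]:
        return iter(self.matrices)

    def __len__(self) -> int:
        return len(self.matrices)

    def get(self, name: str) -> PWM:
        return self._by_name[name]

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.matrices:
            seen.setdefault(m.family, None)
        return list(seen)

    def by_family(self, family: str) -> list[PWM]:
        return [m for m in self.matrices if m.family == family]

    @property
    def max_length(self) -> int:
        return max(len(m) for m in self.matrices)

    # -- PFM text serialization -------------------------------------------

    def to_pfm_text(self) -> str:
        lines: list[str] = []
        for m in self.matrices:
            lines.append(f">{m.name} {m.family}")
            for b, base in enumerate(ALPHABET):
                row = " ".join(str(int(round(c))) for c in m.counts[:, b])
                lines.append(f"{base} {row}")
        return "\n".join(lines) + "\n"

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_pfm_text())

    @classmethod
    def from_pfm_text(
        cls, text: str, pseudocount: float = DEFAULT_PSEUDOCOUNT
    ) -> "PWMLibrary":
        """Parse a JASPAR-style PFM library.

        Each record is ``>NAME FAMILY`` followed by either four base-major
        rows (``A 17 1 ...``) or L position-major rows of 4 counts.
        """
        matrices: list[PWM] = []
        block: list[str] = []
        header: tuple[str, str] | None = None

        def flush() -> None:
            if header is None:
                return
            if not block:
                raise ValueError(f"matrix {header[0]}: no count rows")
            first = block[0].split()
            if first[0].upper() in _BASE_TO_INDEX:
                if len(block) != 4:
                    raise ValueError(f"matrix {header[0]}: expected 4 base rows")
                rows = {}
                for line in block:
                    toks = line.split()
                    rows[toks[0].upper()] = [float(t) for t in toks[1:]]
                counts = np.array([rows[b] for b in ALPHABET]).T
            else:
                counts = np.array([[float(t) for t in line.split()] for line in block])
            matrices.append(
                PWM(header[0], header[1], counts, pseudocount=pseudocount)
            )

        for raw in text.splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                toks = line[1:].split()
                header = (toks[0], toks[1] if len(toks) > 1 else toks[0])
                block = []
            else:
                block.append(line)
        flush()
        return cls(matrices)

    @classmethod
    def read(
        cls, path: Union[str, Path], pseudocount: float = DEFAULT_PSEUDOCOUNT
    ) -> "PWMLibrary":
        return cls.from_pfm_text(Path(path).read_text(), pseudocount=pseudocount)


# -- scanning ---------------------------------------------------------------


def _resolve_threshold(thresholds, name: str) -> float:
    if thresholds is None:
        return DEFAULT_MATRIX_THRESHOLD
    if isinstance(thresholds, Mapping):
        return float(thresholds.get(name, DEFAULT_MATRIX_THRESHOLD))
    return float(thresholds)


def scan_sequence(
    library: PWMLibrary,
    seq: str,
    core_cut: float = DEFAULT_CORE_CUT,
    thresholds: Union[float, Mapping[str, float], None] = None,
    tss_offset: int = DEFAULT_TSS_OFFSET,
) -> list[TFBSHit]:
    """Scan every window of ``seq`` on both strands against every matrix.

    A hit is retained iff ``core_similarity >= core_cut`` and
    ``matrix_similarity >=`` the matrix threshold.  Windows containing
    non-ACGT bases are skipped.  Hits are sorted by start, then matrix name,
    then strand, for reproducible output.
    """
    if len(library) == 0:
        raise ValueError("empty PWM library")
    if len(seq) < library.max_length:
        raise ValueError(
            f"sequence length {len(seq)} shorter than longest matrix "
            f"({library.max_length})"
        )
    n = len(seq)
    enc_fwd = encode_sequence(seq)
    enc_rev = encode_sequence(reverse_complement(seq))
    hits: list[TFBSHit] = []
    for pwm in library:
        thr = _resolve_threshold(thresholds, pwm.name)
        L = len(pwm)
        for strand, enc in (("+", enc_fwd), ("-", enc_rev)):
            if n < L:
                continue
            windows = sliding_window_view(enc, L)
            valid = (windows >= 0).all(axis=1)
            idx = np.flatnonzero(valid)
            if idx.size == 0:
                continue
            msim, csim = pwm._scores_encoded(windows[idx])
            keep = (csim >= core_cut - _EPS) & (msim >= thr - _EPS)
            for j, m, c in zip(idx[keep], msim[keep], csim[keep]):
                start = int(j) if strand == "+" else n - int(j) - L
                hits.append(
                    TFBSHit(
                        start=start,
                        matrix=pwm.name,
                        strand=strand,
                        family=pwm.family,
                        width=L,
                        position_rel_tss=start - tss_offset,
                        core_similarity=float(c),
                        matrix_similarity=float(m),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.matrix, h.strand))
    return hits


# -- background calibration -------------------------------------------------


def random_background(
    length: int, gc: float = 0.41, seed: int = 0
) -> str:
    """I.i.d. nucleotide background with the given GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(ALPHABET[i] for i in idx)


class CalibrationResult(NamedTuple):
    threshold: float
    unreachable: bool
    background_hits: int


def _background_matrix_sims(
    pwm: PWM, background: str, core_cut: float
) -> np.ndarray:
    """Matrix similarities of all both-strand background windows passing the
    core cut."""
    sims = []
    for enc in (encode_sequence(background), encode_sequence(reverse_complement(background))):
        windows = sliding_window_view(enc, len(pwm))
        valid = (windows >= 0).all(axis=1)
        msim, csim = pwm._scores_encoded(windows[valid])
        sims.append(msim[csim >= core_cut - _EPS])
    return np.concatenate(sims)


def calibrate_optimized_threshold(
    pwm: PWM,
    background_gc: float = 0.41,
    target_rate: float = 3.0,
    seed: int = 0,
    background_length: int = 100_000,
    core_cut: float = DEFAULT_CORE_CUT,
    grid: np.ndarray = THRESHOLD_GRID,
) -> CalibrationResult:
    """Smallest grid threshold at which a seeded random background yields at
    most ``target_rate`` matches per 10 kb (core cut applied).

    Returns threshold 1.0 with ``unreachable=True`` when even a perfect-match
    requirement exceeds the target rate.
    """
    if background_length < 100 * len(pwm):
        raise ValueError("background_length must be >= 100 x motif length")
    background = random_background(background_length, gc=background_gc, seed=seed)
    sims = np.sort(_background_matrix_sims(pwm, background, core_cut))
    allowed = target_rate * background_length / 10_000.0
    hits = sims.size
    for t in grid:
        hits = int(sims.size - np.searchsorted(sims, t - _EPS, side="left"))
        if hits <= allowed:
            return CalibrationResult(float(t), False, hits)
    return CalibrationResult(1.0, True, hits)


def calibrate_library(
    library: PWMLibrary,
    background_gc: float = 0.41,
    target_rate: float = 3.0,
    seed: int = 0,
    background_length: int = 100_000,
    core_cut: float = DEFAULT_CORE_CUT,
) -> dict[str, float]:
    """Per-matrix optimized thresholds for a whole library."""
    return {
        m.name: calibrate_optimized_threshold(
            m,
            background_gc=background_gc,
            target_rate=target_rate,
            seed=seed,
            background_length=background_length,
            core_cut=core_cut,
        ).threshold
        for m in library
    }


# -- tabular IO -------------------------------------------------------------

HITS_COLUMNS = [
    "region_id",
    "matrix",
    "family",
    "start",
    "position_rel_tss",
    "strand",
    "core_sim",
    "matrix_sim",
]


def write_hits_tsv(hits_by_region: Mapping[str, Sequence[TFBSHit]], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HITS_COLUMNS) + "\n")
        for region_id in hits_by_region:
            for h in hits_by_region[region_id]:
                fh.write(
                    f"{region_id}\t{h.matrix}\t{h.family}\t{h.start}\t"
                    f"{h.position_rel_tss}\t{h.strand}\t"
                    f"{h.core_similarity:.6f}\t{h.matrix_similarity:.6f}\n"
                )


def read_hits_tsv(path, library: PWMLibrary) -> dict[str, list[TFBSHit]]:
    """Read a hits table back; matrix widths are recovered from the library."""
    out: dict[str, list[TFBSHit]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != HITS_COLUMNS:
            raise ValueError(f"unexpected hits columns: {header}")
        for line in fh:
            region_id, matrix, family, start, rel, strand, csim, msim = (
                line.rstrip("\n").split("\t")
            )
            out.setdefault(region_id, []).append(
                TFBSHit(
                    start=int(start),
                    matrix=matrix,
                    strand=strand,
                    family=family,
                    width=len(library.get(matrix)),
                    position_rel_tss=int(rel),
                    core_similarity=float(csim),
                    matrix_similarity=float(msim),
                )
            )
    return out


def write_thresholds_tsv(thresholds: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("matrix\tthreshold\n")
        for name in thresholds:
            fh.write(f"{name}\t{thresholds[name]:.2f}\n")


def read_thresholds_tsv(path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            name, thr = line.split()
            out[name] = float(thr)
    return out
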
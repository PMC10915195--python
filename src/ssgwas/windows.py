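"""SNP windows of contiguous markers and their variance aggregation.

Overlapping windows of size w shift by one marker (SNP 1-10, 2-11, ...);
non-overlapping windows shift by w (SNP 1-10, 11-20, ...), keeping a final
partial window when the chromosome's marker count is not a multiple of w.
Windows never span chromosomes and are defined on marker index, not base
pairs.  A window's additive variance Var(a_i) is the sum of its markers'
per-SNP variance contributions, and the reported percentage is
Var(a_i) / sigma_a^2 * 100.  Markers are selected when they belong to at
least one window whose percentage reaches the per-size threshold
(inclusive): 0.001% for size 1, 0.01% for 10, 0.03% for 30, 0.05% for 50
and 0.1% for 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataError, DEFAULT_THRESHOLDS
from .effects import SNPEffectSet

MODES = ("overlapping", "non_overlapping")


def default_threshold(w: int) -> float:
    """Per-size minimum percentage of additive variance for selection."""
    if w not in DEFAULT_THRESHOLDS:
        raise DataError(f"no default selection threshold for window size {w}; "
                        "supply one explicitly")
    return DEFAULT_THRESHOLDS[w]


@dataclass
class WindowScheme:
    """All windows of one (size, mode) over a marker map.

    ``windows`` has one row per window with global row indices into the
    marker map (``start``..``end`` inclusive) plus the chromosome.
    """

    size: int
    mode: str
    windows: pd.DataFrame
    n_markers: int

    @property
    def label(self) -> str:
        return f"SW{self.size}_{'overlap' if self.mode == 'overlapping' else 'nonoverlap'}"

    def __len__(self) -> int:
        return len(self.windows)

    def membership_counts(self) -> np.ndarray:
        """How many windows contain each marker (brute-force independent of
        the closed form, used by the conservation diagnostics)."""
        c = np.zeros(self.n_markers, dtype=int)
        for r in self.windows.itertuples():
            c[r.start:r.end + 1] += 1
        return c


def build_windows(marker_map: pd.DataFrame, w: int, mode: str) -> WindowScheme:
    """Construct the windows of one size and mode.

    Per chromosome with m markers: overlapping gives m - w + 1 windows (none
    when m < w); non-overlapping gives ceil(m / w) windows, the last one
    partial.  Size 1 makes the two modes identical.
    """
    if w < 1:
        raise DataError("window size must be >= 1")
    if mode not in MODES:
        raise DataError(f"mode must be one of {MODES}")
    if not len(marker_map):
        raise DataError("empty marker map")
    rows = []
    wid = 0
    offset = 0
    for chrom, sub in marker_map.groupby("chrom", sort=False):
        m = len(sub)
        if mode == "overlapping":
            starts = range(0, m - w + 1)
            for s in starts:
                rows.append((f"win{wid:06d}", str(chrom), offset + s, offset + s + w - 1))
                wid += 1
        else:
            for s in range(0, m, w):
                e = min(s + w, m) - 1
                rows.append((f"win{wid:06d}", str(chrom), offset + s, offset + e))
                wid += 1
        offset += m
    win = pd.DataFrame(rows, columns=["window_id", "chrom", "start", "end"])
    win = win.astype({"start": int, "end": int})
    return WindowScheme(w, mode, win, len(marker_map))


def aggregate(scheme: WindowScheme, snp_vars: SNPEffectSet) -> pd.DataFrame:
    """Window variance table: Var(a_i) = sum of member markers' variances,
    pct = Var(a_i) / sigma_a^2 * 100, one row per window per trait."""
    if scheme.n_markers != len(snp_vars.marker_map):
        raise DataError("window scheme and SNP set use different marker maps")
    if (snp_vars.sigma_a2 <= 0).any():
        raise DataError("sigma_a2 must be positive")
    if not len(scheme.windows):
        return pd.DataFrame(columns=["window_id", "chrom", "start", "end",
                                     "start_bp", "end_bp", "trait", "var_ai", "pct"])
    csum = np.vstack([np.zeros((1, len(snp_vars.traits))),
                      np.cumsum(snp_vars.variances, axis=0)])
    start = scheme.windows["start"].to_numpy()
    end = scheme.windows["end"].to_numpy()
    var_ai = csum[end + 1] - csum[start]                    # n_windows x T
    pos = snp_vars.marker_map["pos"].to_numpy()
    frames = []
    for k, t in enumerate(snp_vars.traits):
        df = scheme.windows.copy()
        df["start_bp"] = pos[start]
        df["end_bp"] = pos[end]
        df["trait"] = t
        df["var_ai"] = var_ai[:, k]
        df["pct"] = var_ai[:, k] / snp_vars.sigma_a2[k] * 100.0
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def select_snps(table: pd.DataFrame, scheme: WindowScheme,
                threshold_pct: float | None = None,
                marker_map: pd.DataFrame | None = None) -> dict[str, set[str]]:
    """Markers lying in at least one window with pct >= threshold, per trait.

    ``table`` is the output of :func:`aggregate`; the threshold defaults to
    the size's standard value.
    """
    if threshold_pct is None:
        threshold_pct = default_threshold(scheme.size)
    if threshold_pct < 0:
        raise DataError("threshold must be >= 0")
    mm = marker_map
    out: dict[str, set[str]] = {}
    for trait, sub in table.groupby("trait", sort=False):
        passing = sub.loc[sub["pct"] >= threshold_pct]
        idx: set[int] = set()
        for r in passing.itertuples():
            idx.update(range(r.start, r.end + 1))
        if mm is not None:
            out[trait] = set(mm["marker"].iloc[sorted(idx)])
        else:
            out[trait] = idx  # type: ignore[assignment]
    return out


def build_all_schemes(marker_map: pd.DataFrame, sizes, modes) -> list[WindowScheme]:
    return [build_windows(marker_map, w, mode) for mode in modes for w in sizes]
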
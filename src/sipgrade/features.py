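"""Gradient-profile parsing and classification features.

Reads per-contig, per-fraction average read depth tables in the column
layout emitted by ``jgi_summarize_bam_contig_depths`` and turns each
contig's observed gradient profile, together with its GC-matched
simulated null profile, into the fixed 24-feature vector consumed by the
enrichment classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gradient import FractionLayout, simulate_null_profile


class DepthTableError(ValueError):
    """The depth table is missing a required column or is malformed."""


class ZeroDepthProfile(ValueError):
    """All-zero depth vector: an undetermined-candidate, not a silent NaN."""


#: Fixed feature order of the classifier input (length 24).
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"obs_rel_{i}" for i in range(1, 9)]
    + [f"null_rel_{i}" for i in range(1, 9)]
    + [
        "n_maxima_obs",
        "n_minima_obs",
        "argmax_obs",
        "argmin_obs",
        "n_maxima_null",
        "argmax_null",
        "mean_fraction_shift",
        "log_total_depth",
    ]
)


@dataclass
class ObservedProfile:
    """One contig's read depths across the sequenced gradient window."""

    contig_id: str
    depths: np.ndarray  # sequenced-window order (heavy -> light), >= 0
    total_depth: float
    length: int
    gc: float | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if np.any(self.depths < 0):
            raise DepthTableError(f"negative depth for contig {self.contig_id}")


def parse_depth_table(path, layout: FractionLayout | None = None) -> list[ObservedProfile]:
    """Parse a jgi-style depth table into one ObservedProfile per row.

    Expects columns ``contigName``, ``contigLen``, ``totalAvgDepth`` and one
    depth column per sequenced fraction named ``F<id>``; per-fraction
    variance columns (``F<id>-var``) are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("contigName", "contigLen", "totalAvgDepth"):
        if col not in df.columns:
            raise DepthTableError(f"depth table missing required column '{col}'")
    if layout is not None:
        frac_cols = [f"F{f}" for f in layout.sequenced_window]
    else:
        frac_cols = [
            c for c in df.columns
            if c.startswith("F") and not c.endswith("-var") and c[1:].isdigit()
        ]
    missing = [c for c in frac_cols if c not in df.columns]
    if missing:
        raise DepthTableError(f"depth table missing fraction column '{missing[0]}'")
    depth_mat = df[frac_cols].to_numpy(dtype=float)
    profiles = []
    for i in range(len(df)):
        profiles.append(
            ObservedProfile(
                contig_id=str(df["contigName"].iat[i]),
                depths=depth_mat[i],
                total_depth=float(df["totalAvgDepth"].iat[i]),
                length=int(df["contigLen"].iat[i]),
            )
        )
    return profiles


def normalize_profile(depths: np.ndarray) -> np.ndarray:
    """Relative profile summing to 1; raises ZeroDepthProfile on all-zero input."""
    depths = np.asarray(depths, dtype=float)
    total = depths.sum()
    if total <= 0:
        raise ZeroDepthProfile("profile has zero total depth")
    return depths / total


def local_extrema(rel_profile: np.ndarray) -> tuple[list[int], list[int]]:
    """Local maxima and minima indices of a profile, with plateau collapsing.

    An interior point is an extremum iff strictly greater (resp. less)
    than both neighbours; runs of equal values collapse to a single
    extremum at the plateau's leftmost index; endpoints are extrema iff
    strictly greater/less than their single neighbour.
    """
    x = np.asarray(rel_profile, dtype=float)
    if x.size < 2:
        raise ValueError("profile must have length >= 2")
    # compress plateaus into runs of (value, start index)
    run_vals, run_starts = [x[0]], [0]
    for i in range(1, x.size):
        if x[i] != run_vals[-1]:
            run_vals.append(x[i])
            run_starts.append(i)
    maxima, minima = [], []
    n = len(run_vals)
    if n == 1:  # single global plateau: no strict neighbour anywhere
        return maxima, minima
    for j in range(n):
        v = run_vals[j]
        left = run_vals[j - 1] if j > 0 else None
        right = run_vals[j + 1] if j < n - 1 else None
        gt = all(v > o for o in (left, right) if o is not None)
        lt = all(v < o for o in (left, right) if o is not None)
        if gt:
            maxima.append(run_starts[j])
        elif lt:
            minima.append(run_starts[j])
    return maxima, minima


def _weighted_mean_position(rel: np.ndarray) -> float:
    return float(np.dot(np.arange(rel.size), rel))


def extract_features(observed: ObservedProfile, null_window: np.ndarray) -> pd.Series:
    """24-dimensional feature vector for one contig.

    Features, in order: the observed relative depth in each of the 8
    window fractions; the null (natural-abundance) relative depth in each;
    counts of local maxima/minima and global argmax/argmin positions of
    the observed profile; the null's maxima count and argmax; the
    depth-weighted mean-fraction shift (observed − null, in fraction
    positions, negative when mass moved toward the heavy end); and
    log10(1 + total depth).

    The null profile is renormalized over the sequenced window before
    comparison, since observed depths exist only there.  An all-zero
    observed profile (flagged upstream as an undetermined candidate)
    yields zero relative depths, zero extrema counts and sentinel −1
    positions.
    """
    null_window = np.asarray(null_window, dtype=float)
    if null_window.size != observed.depths.size:
        raise ValueError(
            f"window mismatch: observed {observed.depths.size}, null {null_window.size}"
        )
    null_rel = normalize_profile(null_window)
    n_max_null, _ = local_extrema(null_rel)
    try:
        obs_rel = normalize_profile(observed.depths)
    except ZeroDepthProfile:
        values = np.concatenate(
            [
                np.zeros(observed.depths.size),
                null_rel,
                [0, 0, -1, -1, len(n_max_null), float(np.argmax(null_rel)), 0.0,
                 np.log10(1.0 + observed.total_depth)],
            ]
        )
        return pd.Series(values, index=list(FEATURE_NAMES), name=observed.contig_id)

    maxima, minima = local_extrema(obs_rel)
    shift = _weighted_mean_position(obs_rel) - _weighted_mean_position(null_rel)
    values = np.concatenate(
        [
            obs_rel,
            null_rel,
            [
                len(maxima),
                len(minima),
                float(np.argmax(obs_rel)),
                float(np.argmin(obs_rel)),
                len(n_max_null),
                float(np.argmax(null_rel)),
                shift,
                np.log10(1.0 + observed.total_depth),
            ],
        ]
    )
    return pd.Series(values, index=list(FEATURE_NAMES), name=observed.contig_id)


def feature_table(
    profiles: list[ObservedProfile],
    gc_by_contig: dict[str, float],
    layout: FractionLayout,
    sigma0: float = 0.005,
    l0: float = 10_000,
) -> pd.DataFrame:
    """Feature matrix (contigs × 24) from observed profiles and contig GC.

    Null profiles depend only on (gc, length, layout); contigs sharing
    both get identical null features.
    """
    rows = []
    for prof in profiles:
        gc = prof.gc if prof.gc is not None else gc_by_contig[prof.contig_id]
        null_full = simulate_null_profile(gc, prof.length, layout, sigma0=sigma0, l0=l0)
        rows.append(extract_features(prof, null_full[layout.window_slice]))
    return pd.DataFrame(rows)
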
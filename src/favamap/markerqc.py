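"""Marker quality control: segregation-distortion index and missingness filter.

F3 genotype classes are expected at 37.5 : 25 : 37.5 (AA : Aa : aa).  Each
marker's deviation is summarised by a normalized index

    Distortion = (1/2) * sum_i |f_i,obs - f_i,exp| / (1 - min(f_exp)),

which is 0 at the Mendelian expectation and exactly 1 when all mass sits on
the least-expected class (the heterozygote).  Markers at or above the index
threshold (default 0.8) or above the missingness ceiling are dropped before
mapping.  A Pearson chi-square goodness-of-fit test (df = 2, no continuity
correction) against the same expectation provides the distortion profile
reported alongside the maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix

__all__ = [
    "F3_EXPECTED_FREQS",
    "DistortionRecord",
    "genotype_counts",
    "distortion_index",
    "chi2_distortion",
    "filter_markers",
]

#: Expected F3 genotype frequencies (AA, Aa, aa).
F3_EXPECTED_FREQS = np.array([0.375, 0.25, 0.375])


@dataclass
class DistortionRecord:
    marker_id: str
    n_AA: int
    n_AB: int
    n_BB: int
    n_missing: int
    observed_freqs: np.ndarray | None  # None when all calls missing
    distortion_index: float | None
    chi2_statistic: float | None
    chi2_pvalue: float | None
    missing_fraction: float
    kept: bool
    drop_reason: str | None


def genotype_counts(gm: GenotypeMatrix) -> np.ndarray:
    """Per-marker counts of (AA, Aa, aa, missing); shape (n_markers, 4)."""
    out = np.empty((gm.n_markers, 4), dtype=int)
    for k, code in enumerate((0, 1, 2, -1)):
        out[:, k] = (gm.calls == code).sum(axis=1)
    return out


def distortion_index(observed_freqs, expected_freqs=F3_EXPECTED_FREQS) -> float:
    """Normalized segregation-distortion index in [0, 1].

    Half the L1 distance between observed and expected class frequencies,
    scaled by 1 - min(expected) so that the worst case (all mass on the
    least-expected class) scores exactly 1.
    """
    f = np.asarray(observed_freqs, dtype=float)
    e = np.asarray(expected_freqs, dtype=float)
    if f.shape != e.shape:
        raise ValueError("observed and expected frequency vectors differ in length")
    if abs(f.sum() - 1.0) > 1e-6 or np.any(f < -1e-12):
        raise ValueError("observed frequencies must be non-negative and sum to 1")
    return float(0.5 * np.abs(f - e).sum() / (1.0 - e.min()))


def chi2_distortion(counts, expected_freqs=F3_EXPECTED_FREQS) -> tuple[float, float]:
    """Pearson chi-square of genotype counts against the F3 expectation.

    ``counts`` is the (n_AA, n_AB, n_BB) vector over non-missing calls;
    returns (statistic, p-value) with df = 2.
    """
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n <= 0:
        raise ValueError("chi-square test needs at least one non-missing call")
    stat, p = stats.chisquare(c, f_exp=n * np.asarray(expected_freqs, dtype=float))
    return float(stat), float(p)


def qc_records(
    gm: GenotypeMatrix,
    distortion_threshold: float = 0.8,
    max_missing_fraction: float = 0.2,
) -> list[DistortionRecord]:
    """Per-marker QC records with the keep/drop decision applied.

    A marker is dropped when its distortion index is at or above the threshold
    or its missing fraction exceeds the ceiling; all-missing markers are
    flagged (untestable) and dropped.
    """
    counts = genotype_counts(gm)
    n_ind = gm.n_individuals
    records = []
    for marker, (n_aa, n_ab, n_bb, n_miss) in zip(gm.markers, counts):
        n_called = n_aa + n_ab + n_bb
        miss_frac = n_miss / n_ind
        if n_called == 0:
            records.append(
                DistortionRecord(
                    marker, n_aa, n_ab, n_bb, n_miss, None, None, None, None,
                    miss_frac, kept=False, drop_reason="all_missing",
                )
            )
            continue
        freqs = np.array([n_aa, n_ab, n_bb], dtype=float) / n_called
        index = distortion_index(freqs)
        stat, p = chi2_distortion([n_aa, n_ab, n_bb])
        reason = None
        if index >= distortion_threshold:
            reason = "distortion"
        elif miss_frac > max_missing_fraction:
            reason = "missing"
        records.append(
            DistortionRecord(
                marker, n_aa, n_ab, n_bb, n_miss, freqs, index, stat, p,
                miss_frac, kept=reason is None, drop_reason=reason,
            )
        )
    return records


def filter_markers(
    gm: GenotypeMatrix,
    distortion_threshold: float = 0.8,
    max_missing_fraction: float = 0.2,
) -> tuple[GenotypeMatrix, GenotypeMatrix, pd.DataFrame]:
    """Partition markers into kept/dropped and return the QC report.

    Returns ``(kept_matrix, dropped_matrix, report)`` where the report has one
    row per input marker with counts, index, chi-square p and the kept flag.
    """
    if gm.n_markers == 0:
        raise ValueError("empty genotype matrix")
    records = qc_records(gm, distortion_threshold, max_missing_fraction)
    report = pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in records],
            "n_AA": [r.n_AA for r in records],
            "n_AB": [r.n_AB for r in records],
            "n_BB": [r.n_BB for r in records],
            "n_missing": [r.n_missing for r in records],
            "distortion_index": [r.distortion_index for r in records],
            "chi2_p": [r.chi2_pvalue for r in records],
            "kept_flag": [r.kept for r in records],
            "drop_reason": [r.drop_reason for r in records],
        }
    )
    kept_ids = [r.marker_id for r in records if r.kept]
    dropped_ids = [r.marker_id for r in records if not r.kept]
    return gm.subset(kept_ids), gm.subset(dropped_ids), report
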
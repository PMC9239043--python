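"""Allele-frequency trajectories and environmental-covariate correlation.

The trajectory matrix tracks one focal allele per SNV — the most frequent
non-consensus allele in the pooled data across samples — so trajectories
are comparable over time.  Entries where a sample's coverage falls below
the floor are missing, never zero.  SNVs whose frequencies track a
covariate are found by Spearman rank correlation (pairwise-complete,
average ranks for ties) with Benjamini-Hochberg control, restricted to
nonsynonymous SNVs by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import BASES, GenomeAnnotation
from .profiling import PileupTable, call_snvs
from .stats import bh_adjust

DEFAULT_TRAJ_MIN_COVERAGE = 20
DEFAULT_MIN_POINTS = 8


@dataclass
class TrajectoryMatrix:
    """SNVs x samples focal-allele frequencies with an aligned covariate."""

    frequencies: pd.DataFrame     # index: position; columns: sample ids
    covariate: pd.Series          # per sample
    classes: pd.Series            # per position SNV class
    focal_allele: pd.Series       # per position focal base


def snv_frequency_matrix(pileups: dict[str, PileupTable],
                         annotation: GenomeAnnotation,
                         covariate: pd.Series,
                         min_coverage: int = DEFAULT_TRAJ_MIN_COVERAGE,
                         snv_min_coverage: int | None = None
                         ) -> TrajectoryMatrix:
    """Assemble the trajectory matrix over the union of per-sample SNVs.

    The focal allele per site is fixed from the pooled counts (most
    frequent non-consensus base); per-sample frequency is its share of the
    site's total coverage, missing (NaN) below ``min_coverage``."""
    samples = list(pileups)
    missing = [s for s in samples if s not in covariate.index]
    if missing:
        raise ValueError(f"samples without covariate: {missing}")
    snv_cov = min_coverage if snv_min_coverage is None else snv_min_coverage

    positions: set[int] = set()
    classes: dict[int, str] = {}
    for s in samples:
        snvs = call_snvs(pileups[s], annotation, min_coverage=snv_cov)
        for pos, cls in zip(snvs["position"], snvs["snv_class"]):
            positions.add(int(pos))
            # nonsynonymous dominates across samples, as within a site
            if classes.get(int(pos)) != "nonsynonymous":
                classes[int(pos)] = cls
    pos_arr = np.array(sorted(positions), dtype=np.int64)
    if len(pos_arr) == 0:
        empty = pd.DataFrame(index=pd.Index([], name="position"),
                             columns=samples, dtype=float)
        return TrajectoryMatrix(empty, covariate.loc[samples],
                                pd.Series(dtype=object),
                                pd.Series(dtype=object))

    pooled = sum(pileups[s].counts[pos_arr] for s in samples)
    consensus = np.argmax(pooled, axis=1)
    masked = pooled.copy()
    masked[np.arange(len(pos_arr)), consensus] = -1
    focal = np.argmax(masked, axis=1)

    freq = {}
    for s in samples:
        counts = pileups[s].counts[pos_arr]
        cov = counts.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = counts[np.arange(len(pos_arr)), focal] / cov
        f[cov < min_coverage] = np.nan
        freq[s] = f
    frame = pd.DataFrame(freq, index=pd.Index(pos_arr, name="position"))
    return TrajectoryMatrix(
        frame, covariate.loc[samples],
        pd.Series({int(p): classes[int(p)] for p in pos_arr}, name="snv_class"),
        pd.Series({int(p): BASES[focal[i]] for i, p in enumerate(pos_arr)},
                  name="focal_allele"))


def covariate_correlated_snvs(traj: TrajectoryMatrix,
                              min_points: int = DEFAULT_MIN_POINTS,
                              alpha: float = 0.05,
                              classes_tested: tuple[str, ...] =
                              ("nonsynonymous",)) -> pd.DataFrame:
    """Per-SNV Spearman correlation of focal-allele frequency with the
    covariate; BH over tested SNVs, flag at adjusted p < ``alpha``.

    SNVs outside ``classes_tested`` or with fewer than ``min_points``
    non-missing observations are reported untested."""
    cov = traj.covariate.to_numpy(float)
    rows = []
    for pos, freqs in traj.frequencies.iterrows():
        cls = traj.classes.get(int(pos))
        f = freqs.to_numpy(float)
        ok = ~np.isnan(f)
        testable = cls in classes_tested and int(ok.sum()) >= min_points
        if testable:
            rho, p = stats.spearmanr(f[ok], cov[ok])
            if np.isnan(rho):     # constant frequency vector
                testable, rho, p = False, np.nan, np.nan
        else:
            rho, p = np.nan, np.nan
        rows.append((int(pos), cls, int(ok.sum()), testable, rho, p))
    out = pd.DataFrame(rows, columns=[
        "position", "snv_class", "n_points", "tested", "rho", "p",
    ]).set_index("position")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["correlated"] = out["adj_p"] < alpha
    return out
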
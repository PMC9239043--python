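"""Linkage disequilibrium between SNV pairs co-observed on read pairs.

Two SNVs are linked through the read pairs ("connecting pairs") that carry a
called allele at both sites; the two mates of a pair are pooled, so an
allele seen on either mate counts, and a pair observing conflicting bases
at one site is discarded for pairs involving that site.  Each SNV is
projected to its two top alleles (consensus + most frequent minor).  r^2 is
the squared correlation of the 2x2 joint haplotype table and is normalised
by rarefying the connecting pairs to a fixed count so that values are
comparable across coverage levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reads import ReadPairSet

DEFAULT_MAX_DIST = 420
DEFAULT_MIN_CONNECTING = 20
DEFAULT_RAREFY_TO = 20
DEFAULT_N_REPS = 100
DEFAULT_BIN_WIDTH = 30

_DISCORDANT = -2
_MISSING = -1


@dataclass
class LinkagePair:
    """Joint observation of two biallelic SNVs on connecting read pairs.

    Counts are (n_AB, n_Ab, n_aB, n_ab) where A/B are the major (consensus)
    alleles at the left and right site."""

    pos1: int
    pos2: int
    class_pair: str | None
    n_ab: tuple[int, int, int, int]
    r2_raw: float
    r2_rarefied: float = np.nan

    @property
    def distance(self) -> int:
        return self.pos2 - self.pos1

    @property
    def n_connecting(self) -> int:
        return sum(self.n_ab)


def raw_r2(n_ab: tuple[int, int, int, int]) -> float:
    """r^2 = (f_AB - f_A f_B)^2 / (f_A(1-f_A) f_B(1-f_B)); NaN when either
    margin is monomorphic."""
    n11, n10, n01, n00 = n_ab
    n = n11 + n10 + n01 + n00
    if n == 0:
        return np.nan
    fa = (n11 + n10) / n
    fb = (n11 + n01) / n
    denom = fa * (1 - fa) * fb * (1 - fb)
    if denom == 0:
        return np.nan
    d = n11 / n - fa * fb
    return d * d / denom


def r_squared_rarefied(n_ab: tuple[int, int, int, int],
                       subsample_size: int = DEFAULT_RAREFY_TO,
                       n_reps: int = DEFAULT_N_REPS,
                       seed: int = 0,
                       rng: np.random.Generator | None = None) -> float:
    """Mean raw r^2 over ``n_reps`` subsamples of exactly ``subsample_size``
    connecting pairs drawn without replacement.

    Subsamples with a monomorphic margin are skipped and redrawn (at most
    ``10 * n_reps`` attempts); if no valid subsample is found the value is
    undefined (NaN).  When the full table has exactly ``subsample_size``
    pairs the rarefied value equals the raw value."""
    counts = np.asarray(n_ab, dtype=np.int64)
    total = int(counts.sum())
    if total < subsample_size:
        raise ValueError(
            f"{total} connecting pairs < subsample size {subsample_size}")
    if total == subsample_size:
        return raw_r2(tuple(counts))
    if rng is None:
        rng = np.random.default_rng(seed)
    values = []
    attempts = 0
    while len(values) < n_reps and attempts < 10 * n_reps:
        attempts += 1
        sub = rng.multivariate_hypergeometric(counts, subsample_size)
        r2 = raw_r2(tuple(sub))
        if not np.isnan(r2):
            values.append(r2)
    return float(np.mean(values)) if values else np.nan


def _site_observations(snvs: pd.DataFrame, reads: ReadPairSet
                       ) -> dict[int, np.ndarray]:
    """Per SNV site, a length-n_pairs vector of allele codes: 0 = major,
    1 = minor, -1 = missing/other, -2 = discordant mates."""
    obs: dict[int, np.ndarray] = {}
    rl = reads.read_len
    for row in snvs.itertuples(index=False):
        pos = row.position
        major, minor = row.major_code, row.minor_code
        alleles = np.full(reads.n_pairs, _MISSING, dtype=np.int8)
        seen = np.zeros(reads.n_pairs, dtype=bool)
        for starts, seqs in ((reads.start1, reads.seq1),
                             (reads.start2, reads.seq2)):
            off = pos - starts
            cover = (off >= 0) & (off < rl)
            rows_ = np.where(cover)[0]
            base = seqs[rows_, off[rows_]]
            call = np.where(base == major, 0,
                            np.where(base == minor, 1, _MISSING)).astype(np.int8)
            fresh = ~seen[rows_]
            alleles[rows_[fresh]] = call[fresh]
            dup = rows_[~fresh]
            conflict = alleles[dup] != call[~fresh]
            alleles[dup[conflict]] = _DISCORDANT
            seen[rows_] = True
        obs[int(pos)] = alleles
    return obs


_CLASS_CODE = {"nonsynonymous": "N", "synonymous": "S"}


def enumerate_linked_pairs(snvs: pd.DataFrame, reads: ReadPairSet,
                           max_dist: int = DEFAULT_MAX_DIST,
                           min_connecting_pairs: int = DEFAULT_MIN_CONNECTING,
                           coding_only: bool = True,
                           rarefy_to: int = DEFAULT_RAREFY_TO,
                           n_reps: int = DEFAULT_N_REPS,
                           seed: int = 0) -> list[LinkagePair]:
    """All SNV pairs up to ``max_dist`` apart with at least
    ``min_connecting_pairs`` connecting read pairs, with raw and rarefied
    r^2 and N-N/N-S/S-S stratification (coding SNVs only by default)."""
    table = snvs[snvs["gene_id"].notna()] if coding_only else snvs
    table = table.sort_values("position")
    if len(table) < 2:
        return []
    obs = _site_observations(table, reads)
    positions = table["position"].to_numpy()
    classes = table["snv_class"].to_numpy()
    rng = np.random.default_rng(seed)

    out: list[LinkagePair] = []
    for i in range(len(positions)):
        oi = obs[int(positions[i])]
        valid_i = oi >= 0
        for j in range(i + 1, len(positions)):
            dist = int(positions[j] - positions[i])
            if dist > max_dist:
                break
            if dist == 0:
                continue
            oj = obs[int(positions[j])]
            both = valid_i & (oj >= 0)
            n = int(both.sum())
            if n < min_connecting_pairs:
                continue
            a, b = oi[both], oj[both]
            n11 = int(((a == 0) & (b == 0)).sum())
            n10 = int(((a == 0) & (b == 1)).sum())
            n01 = int(((a == 1) & (b == 0)).sum())
            n00 = n - n11 - n10 - n01
            counts = (n11, n10, n01, n00)
            ci = _CLASS_CODE.get(classes[i])
            cj = _CLASS_CODE.get(classes[j])
            cls = "-".join(sorted((ci, cj))) if ci and cj else None
            pair = LinkagePair(int(positions[i]), int(positions[j]), cls,
                               counts, raw_r2(counts))
            # rarefaction needs at least rarefy_to connecting pairs; with a
            # lower retention threshold the normalised value is undefined
            pair.r2_rarefied = r_squared_rarefied(
                counts, rarefy_to, n_reps, rng=rng) \
                if n >= rarefy_to else np.nan
            out.append(pair)
    return out


def pairs_to_frame(pairs: list[LinkagePair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pos1": p.pos1, "pos2": p.pos2, "distance": p.distance,
        "class_pair": p.class_pair,
        "n_AB": p.n_ab[0], "n_Ab": p.n_ab[1],
        "n_aB": p.n_ab[2], "n_ab": p.n_ab[3],
        "n_connecting": p.n_connecting,
        "r2_raw": p.r2_raw, "r2_rarefied": p.r2_rarefied,
    } for p in pairs])


def linkage_decay_curve(pairs: list[LinkagePair],
                        bin_width: int = DEFAULT_BIN_WIDTH,
                        max_dist: int = DEFAULT_MAX_DIST) -> pd.DataFrame:
    """Distance-binned unweighted mean rarefied r^2, per class stratum plus
    an 'all' stratum; empty bins carry NaN and a zero pair count."""
    edges = np.arange(0, max_dist + bin_width, bin_width)
    rows = []
    frame = pairs_to_frame(pairs) if pairs else pd.DataFrame(
        columns=["distance", "class_pair", "r2_rarefied"])
    strata = ["all"] + sorted(
        {p.class_pair for p in pairs if p.class_pair is not None})
    for stratum in strata:
        sub = frame if stratum == "all" else frame[frame["class_pair"] == stratum]
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = sub[(sub["distance"] > lo) & (sub["distance"] <= hi)]
            vals = in_bin["r2_rarefied"].dropna()
            rows.append({
                "stratum": stratum, "bin_start": int(lo), "bin_end": int(hi),
                "mean_r2": float(vals.mean()) if len(vals) else np.nan,
                "n_pairs": int(len(in_bin)),
            })
    return pd.DataFrame(rows)


def mean_genome_r2(pairs: list[LinkagePair]) -> float:
    """Unweighted mean rarefied r^2 over all retained pairs (all strata)."""
    vals = [p.r2_rarefied for p in pairs if not np.isnan(p.r2_rarefied)]
    if not vals:
        raise ValueError("no retained SNV pairs with defined r^2")
    return float(np.mean(vals))
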
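"""Window-variance genome scan.

The detection statistic is the across-individual variance of the GEBV
contributed by a sliding window of consecutive SNPs (default 10, step 1,
windows never spanning chromosomes). For 1-SNP windows this reduces to the
classic per-SNP variance alpha_j^2 Var_i(X_ij). Significant overlapping
windows are merged into regions; within a region, distinct single-SNP
variance peaks separated by a deep enough dip are reported as distinct QTL,
each positioned at the SNP with the largest single-SNP variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popsim import GeneticMap


@dataclass
class WindowScan:
    chrom: np.ndarray            # per window
    first_snp_index: np.ndarray  # global SNP index of the window's first SNP
    variance: np.ndarray         # trait-units^2, across-individual, ddof=1
    window_size: int
    step: int

    @property
    def n_windows(self) -> int:
        return self.variance.size

    def to_frame(self, gmap: GeneticMap | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom,
                           "first_snp_index": self.first_snp_index,
                           "variance": self.variance})
        if gmap is not None:
            df.insert(1, "first_snp_id", gmap.snp_id[self.first_snp_index])
        return df


def _window_starts(gmap: GeneticMap, window_size: int, step: int):
    for c, sl in gmap.chrom_slices():
        m_c = sl.stop - sl.start
        if m_c < window_size:
            warnings.warn(f"chromosome {c} has {m_c} SNPs < window size "
                          f"{window_size}; no windows emitted")
            continue
        yield c, sl, range(sl.start, sl.stop - window_size + 1, step)


def window_variances(alpha: np.ndarray, X_ref: np.ndarray, gmap: GeneticMap,
                     window_size: int = 10, step: int = 1) -> WindowScan:
    """Across-individual variance of w_il = sum_{j in window} X_ij alpha_j."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    X_ref = np.asarray(X_ref, float)
    if X_ref.shape[0] < 2:
        raise ValueError("need at least 2 reference individuals")
    alpha = np.asarray(alpha, float)
    contrib = X_ref * alpha                       # (n, m)
    chroms, firsts, variances = [], [], []
    for c, sl, starts in _window_starts(gmap, window_size, step):
        cum = np.zeros((X_ref.shape[0], sl.stop - sl.start + 1))
        np.cumsum(contrib[:, sl], axis=1, out=cum[:, 1:])
        for t in starts:
            k = t - sl.start
            w = cum[:, k + window_size] - cum[:, k]
            chroms.append(c)
            firsts.append(t)
            variances.append(np.var(w, ddof=1))
    return WindowScan(np.array(chroms), np.array(firsts),
                      np.array(variances, float), window_size, step)


def single_snp_variances(alpha: np.ndarray, X_ref: np.ndarray) -> np.ndarray:
    """alpha_j^2 Var_i(X_ij) — the 1-SNP-window statistic, per SNP."""
    X_ref = np.asarray(X_ref, float)
    return np.asarray(alpha, float) ** 2 * np.var(X_ref, axis=0, ddof=1)


def window_variances_per_sample(chain: np.ndarray, X_ref: np.ndarray,
                                gmap: GeneticMap, window_size: int = 10,
                                step: int = 1) -> WindowScan:
    """Per-MCMC-sample window variances averaged over the stored chain.

    For each posterior sample s, the across-individual variance of the
    window GEBV is a' C a with C the genotype covariance of the window's
    columns; averaging over samples uses the banded second-moment matrix of
    the chain, so the cost is O(S m w) rather than O(S n m).
    """
    if chain is None:
        raise ValueError("no stored chain: re-run the fit with store_chain=True")
    chain = np.asarray(chain, float)
    if chain.ndim != 2:
        raise ValueError("chain must be (samples, snps)")
    X_ref = np.asarray(X_ref, float)
    m = chain.shape[1]
    Xc = X_ref - X_ref.mean(axis=0)
    n = X_ref.shape[0]
    # banded covariances of genotype columns and second moments of the chain
    cband = np.zeros((window_size, m))
    m2band = np.zeros((window_size, m))
    for d in range(window_size):
        if d < m:
            cband[d, :m - d] = np.einsum("ij,ij->j", Xc[:, :m - d], Xc[:, d:]) / (n - 1)
            m2band[d, :m - d] = np.mean(chain[:, :m - d] * chain[:, d:], axis=0)
    prod = cband * m2band
    chroms, firsts, variances = [], [], []
    for c, sl, starts in _window_starts(gmap, window_size, step):
        for t in starts:
            v = float(np.sum(prod[0, t:t + window_size]))
            for d in range(1, window_size):
                v += 2.0 * float(np.sum(prod[d, t:t + window_size - d]))
            # clip tiny negative round-off
            chroms.append(c)
            firsts.append(t)
            variances.append(max(v, 0.0))
    return WindowScan(np.array(chroms), np.array(firsts),
                      np.array(variances, float), window_size, step)


@dataclass
class QTLCall:
    chrom: int
    peak_snp_index: int
    peak_snp_id: str
    peak_position_bp: int
    peak_snp_variance: float
    peak_window_variance: float
    tier: str
    member_windows: list[int] = field(default_factory=list)


def _local_maxima(v: np.ndarray) -> list[int]:
    """Indices of local maxima; plateaus contribute their leftmost index."""
    peaks = []
    i = 0
    n = v.size
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok:
            peaks.append(i)
        i = j + 1
    return peaks


def call_qtl(scan: WindowScan, snp_variance: np.ndarray,
             thresholds: dict[str, float], gmap: GeneticMap,
             dip_fraction: float = 0.5) -> list[QTLCall]:
    """Group significant windows into QTL calls.

    Overlapping windows above a tier's threshold form one region; within a
    region, two single-SNP-variance peaks are called as distinct QTL when the
    minimum between them falls below ``dip_fraction`` of the lower peak.
    Each call is positioned at its region's largest single-SNP variance
    (ties to the leftmost SNP).
    """
    if any(t < 0 for t in thresholds.values()):
        raise ValueError("thresholds must be >= 0")
    snp_variance = np.asarray(snp_variance, float)
    calls: list[QTLCall] = []
    for tier, thr in thresholds.items():
        sig = np.flatnonzero(scan.variance > thr)
        if sig.size == 0:
            continue
        # runs of overlapping-or-contiguous windows on one chromosome
        runs: list[list[int]] = [[int(sig[0])]]
        for w in sig[1:]:
            prev = runs[-1][-1]
            same_chrom = scan.chrom[w] == scan.chrom[prev]
            overlap = scan.first_snp_index[w] <= \
                scan.first_snp_index[prev] + scan.window_size
            if same_chrom and overlap:
                runs[-1].append(int(w))
            else:
                runs.append([int(w)])
        for run in runs:
            lo = int(scan.first_snp_index[run[0]])
            hi = int(scan.first_snp_index[run[-1]]) + scan.window_size - 1
            v = snp_variance[lo:hi + 1]
            peaks = _local_maxima(v)
            if not peaks:
                peaks = [int(np.argmax(v))]
            groups = [peaks[0]]
            for p in peaks[1:]:
                prev = groups[-1]
                valley = float(np.min(v[prev:p + 1]))
                if valley < dip_fraction * min(v[prev], v[p]):
                    groups.append(p)
                elif v[p] > v[prev]:
                    groups[-1] = p
            for p in groups:
                g = lo + p
                calls.append(QTLCall(
                    chrom=int(scan.chrom[run[0]]), peak_snp_index=g,
                    peak_snp_id=str(gmap.snp_id[g]),
                    peak_position_bp=int(gmap.position_bp[g]),
                    peak_snp_variance=float(v[p]),
                    peak_window_variance=float(np.max(scan.variance[run])),
                    tier=tier, member_windows=[int(scan.first_snp_index[w])
                                               for w in run]))
    return calls


def plot_scan(scan: WindowScan, gmap: GeneticMap, thresholds=None,
              qtl_truth=None, ax=None):
    """Window variance against the first SNP of each window, per chromosome."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    for c in np.unique(scan.chrom):
        sel = scan.chrom == c
        ax.plot(scan.first_snp_index[sel], scan.variance[sel], lw=0.8,
                label=f"chr{c}")
    if thresholds:
        styles = {"primary": "-", "secondary": "--"}
        for tier, thr in thresholds.items():
            ax.axhline(thr, color="k", ls=styles.get(tier, ":"), lw=0.8)
    if qtl_truth is not None:
        ax.plot(qtl_truth, np.zeros(len(qtl_truth)), "rv", ms=4)
    ax.set_xlabel("first SNP of window")
    ax.set_ylabel("window GEBV variance")
    return ax
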
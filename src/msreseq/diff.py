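"""Two-group differential methylation testing.

Methylation scores are converted to pseudo-counts, negative-binomial
overdispersion is estimated by moments with shrinkage toward a common
value, and each site is tested with a conditional NB exact test
(enumerating split probabilities of the per-site total between groups),
followed by Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from msreseq.quantify import MethylationMatrix

#: relative tolerance used to rank split probabilities in the exact test
_TIE_EPS = 1e-8
#: floor applied to tagwise dispersion estimates
_PHI_FLOOR = 1e-3


@dataclass
class CountMatrix:
    """Integer pseudo-counts per (site row x sample) with library sizes."""

    counts: pd.DataFrame  # int values, index site_id, columns samples
    lib_sizes: pd.Series  # column sums

    def normalized(self) -> pd.DataFrame:
        """Counts rescaled to the geometric-mean library size."""
        common = float(np.exp(np.mean(np.log(self.lib_sizes))))
        return self.counts * (common / self.lib_sizes)


def to_counts(matrix: MethylationMatrix, scale: float = 0.05) -> CountMatrix:
    """Round ``value * scale`` to integer counts; record library sizes.

    The default scale turns a typical %-scale score (~60) into a count of
    ~3, matching the library magnitude the test was designed around.
    """
    values = matrix.data.to_numpy()
    if np.any(values < 0):
        raise ValueError("matrix contains negative values")
    counts = pd.DataFrame(
        np.rint(values * scale).astype(np.int64),
        index=matrix.data.index,
        columns=matrix.data.columns,
    )
    lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        bad = list(lib_sizes.index[lib_sizes <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    return CountMatrix(counts=counts, lib_sizes=lib_sizes)


def _group_columns(columns: Sequence[str], groups: Dict[str, str]
                   ) -> Tuple[str, str, List[str], List[str]]:
    """Two group labels in manifest order plus their sample columns."""
    ordered: List[str] = []
    for sample in groups:
        if groups[sample] not in ordered:
            ordered.append(groups[sample])
    if len(ordered) != 2:
        raise ValueError(f"expected exactly 2 groups, got {ordered}")
    g1, g2 = ordered
    s1 = [c for c in columns if groups[c] == g1]
    s2 = [c for c in columns if groups[c] == g2]
    return g1, g2, s1, s2


def _moment_dispersions(norm: pd.DataFrame, s1: List[str], s2: List[str]
                        ) -> np.ndarray:
    """Per-site method-of-moments dispersion on normalized counts."""
    x1 = norm[s1].to_numpy()
    x2 = norm[s2].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    resid1 = x1 - x1.mean(axis=1, keepdims=True)
    resid2 = x2 - x2.mean(axis=1, keepdims=True)
    df = n1 + n2 - 2
    pooled_var = (np.sum(resid1 ** 2, axis=1) + np.sum(resid2 ** 2, axis=1)) / df
    mu = np.concatenate([x1, x2], axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mu > 0, (pooled_var - mu) / np.square(mu), 0.0)
    return np.maximum(phi, 0.0)


def estimate_common_dispersion(cm: CountMatrix, groups: Dict[str, str]) -> float:
    """Median of per-site moment dispersion estimates."""
    _, _, s1, s2 = _group_columns(cm.counts.columns, groups)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("need at least 2 samples per group")
    phi = _moment_dispersions(cm.normalized(), s1, s2)
    return float(np.median(phi))


def estimate_tagwise_dispersion(cm: CountMatrix, groups: Dict[str, str],
                                common_phi: float,
                                prior_weight: float = 10.0) -> np.ndarray:
    """Per-site dispersion shrunk toward the common value.

    ``phi_i = (w * common + df * phi_hat_i) / (w + df)`` with ``df`` the
    residual degrees of freedom; floored at 1e-3.  ``prior_weight = inf``
    returns the common value everywhere; ``0`` returns the raw estimates.
    """
    if prior_weight < 0:
        raise ValueError("prior_weight must be >= 0")
    _, _, s1, s2 = _group_columns(cm.counts.columns, groups)
    raw = _moment_dispersions(cm.normalized(), s1, s2)
    df = len(s1) + len(s2) - 2
    if np.isinf(prior_weight):
        phi = np.full(raw.shape, common_phi)
    else:
        phi = (prior_weight * common_phi + df * raw) / (prior_weight + df)
    return np.maximum(phi, _PHI_FLOOR)


def _split_log_pmf(t: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """Log-probabilities of each split (k, t-k) of the total under the null.

    With per-sample NB dispersion ``phi``, group sums are NB with size
    ``n/phi``; conditional on the total, the split distribution is free of
    the mean.  ``phi = 0`` degenerates to binomial with p = n1/(n1+n2).
    """
    k = np.arange(t + 1, dtype=np.float64)
    if phi <= 0:
        p = n1 / (n1 + n2)
        logpmf = (
            gammaln(t + 1) - gammaln(k + 1) - gammaln(t - k + 1)
            + k * np.log(p) + (t - k) * np.log1p(-p)
        )
    else:
        r1, r2 = n1 / phi, n2 / phi
        logpmf = (
            gammaln(k + r1) - gammaln(k + 1) - gammaln(r1)
            + gammaln(t - k + r2) - gammaln(t - k + 1) - gammaln(r2)
        )
    return logpmf - logsumexp(logpmf)


def exact_nb_test(counts_a: Sequence[float], counts_b: Sequence[float],
                  lib_sizes: Optional[Sequence[float]] = None,
                  phi: float = 0.0) -> float:
    """Two-sided conditional NB exact test for a two-group count split.

    Library sizes, when given, are equalized first (counts rescaled to the
    geometric-mean size, rounded half-to-even).  The two-sided p-value sums
    the probabilities of all splits no more likely than the observed one.
    """
    a = np.asarray(counts_a, dtype=np.float64)
    b = np.asarray(counts_b, dtype=np.float64)
    if lib_sizes is not None:
        sizes = np.asarray(lib_sizes, dtype=np.float64)
        common = float(np.exp(np.mean(np.log(sizes))))
        scaled = np.concatenate([a, b]) * (common / sizes)
        scaled = np.rint(scaled)
        a, b = scaled[: a.size], scaled[a.size:]
    ka, kb = int(round(a.sum())), int(round(b.sum()))
    t = ka + kb
    if t == 0:
        return 1.0
    logpmf = _split_log_pmf(t, a.size, b.size, phi)
    pmf = np.exp(logpmf)
    observed = pmf[ka]
    p = float(np.sum(pmf[pmf <= observed * (1.0 + _TIE_EPS)]))
    return min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def differential_table(matrix: MethylationMatrix, alpha_fdr: float = 0.05,
                       scale: float = 1.0,
                       prior_weight: float = 10.0) -> pd.DataFrame:
    """Full per-site differential chain; returns the sorted result table.

    Columns: ``site_id, logMET, logFC, p_std, p_fdr, response``.  logMET is
    log2 of the mean normalized pseudo-count (+0.5 offset); ``response``
    "up" means a higher normalized count in the second manifest group.
    Summary counts at ``alpha_fdr`` are stored in ``DataFrame.attrs``.
    """
    cm = to_counts(matrix, scale=scale)
    groups = matrix.groups
    g1, g2, s1, s2 = _group_columns(cm.counts.columns, groups)
    common_phi = estimate_common_dispersion(cm, groups)
    phi = estimate_tagwise_dispersion(cm, groups, common_phi, prior_weight)

    # equalize library sizes once for the whole matrix
    common = float(np.exp(np.mean(np.log(cm.lib_sizes))))
    eq = np.rint(cm.counts * (common / cm.lib_sizes)).astype(np.int64)
    a_tot = eq[s1].sum(axis=1).to_numpy()
    b_tot = eq[s2].sum(axis=1).to_numpy()

    n1, n2 = len(s1), len(s2)
    p_raw = np.ones(len(eq))
    for i in range(len(eq)):
        t = int(a_tot[i] + b_tot[i])
        if t == 0:
            continue
        logpmf = _split_log_pmf(t, n1, n2, float(phi[i]))
        pmf = np.exp(logpmf)
        obs = pmf[int(a_tot[i])]
        p_raw[i] = min(float(np.sum(pmf[pmf <= obs * (1.0 + _TIE_EPS)])), 1.0)

    norm = cm.normalized()
    mean_all = norm.mean(axis=1).to_numpy()
    mean_g1 = norm[s1].mean(axis=1).to_numpy()
    mean_g2 = norm[s2].mean(axis=1).to_numpy()
    log_met = np.log2(mean_all + 0.5)
    log_fc = np.log2(mean_g2 + 0.5) - np.log2(mean_g1 + 0.5)
    p_fdr = bh_adjust(p_raw)

    table = pd.DataFrame(
        {
            "site_id": cm.counts.index,
            "logMET": log_met,
            "logFC": log_fc,
            "p_std": p_raw,
            "p_fdr": p_fdr,
            "response": np.where(log_fc >= 0, "up", "down"),
        }
    ).reset_index(drop=True)
    table = table.sort_values(
        ["p_fdr", "p_std", "site_id"], kind="stable"
    ).reset_index(drop=True)
    sig = table["p_fdr"] < alpha_fdr
    table.attrs["group1"] = g1
    table.attrs["group2"] = g2
    table.attrs["alpha_fdr"] = alpha_fdr
    table.attrs["n_significant"] = int(sig.sum())
    table.attrs["n_up"] = int((sig & (table["response"] == "up")).sum())
    table.attrs["n_down"] = int((sig & (table["response"] == "down")).sum())
    return table


def write_diff_table(table: pd.DataFrame, path) -> None:
    with open(path, "w") as out:
        out.write(
            f"# response 'up' = higher methylation signal in group "
            f"'{table.attrs.get('group2', '?')}' (second manifest group)\n"
        )
        table.to_csv(out, sep="\t", index=False, float_format="%.6g")
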
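"""Negative-binomial enrichment calling on clone count tables.

Each experiment's count table (clones x samples over replicates and
cycles) is analyzed independently.  Counts are normalized by
median-of-ratios size factors; per clone, a negative-binomial model with
cycle as a categorical factor is summarized by the last-vs-first-cycle
log2 fold change and a Wald test, with dispersions estimated by method of
moments and shrunk 50/50 in log space toward a fitted mean-dispersion
trend.  P-values are Benjamini-Hochberg adjusted across clones, and
clones are flagged POS (significant increase), NEG (significant
decrease), or NS.  Per-clone flags are combined across experiments into a
strict-majority consensus.

This is a deliberately simple count model in the spirit of the standard
RNA-seq frameworks: it keeps their normalization and test structure but
replaces the empirical-Bayes dispersion machinery with a transparent
moment estimator, which is sufficient for calling the large frequency
changes serial-passage competition produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

FLAGS = ("POS", "NEG", "NS")
_DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample label -> (replicate, cycle); cycle is categorical."""

    samples: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        cycles = {c for _, c in self.samples.values()}
        if len(cycles) < 2:
            raise ValueError("at least 2 cycles required")
        if len(self.samples) < 2:
            raise ValueError("at least 2 samples required")

    @property
    def cycles(self) -> list[int]:
        return sorted({c for _, c in self.samples.values()})

    def cycle_of(self, sample: str) -> int:
        return self.samples[sample][1]

    @classmethod
    def from_labels(cls, labels) -> "ExperimentDesign":
        """Parse ``rep{r}_cyc{c}`` sample labels."""
        out = {}
        for lab in labels:
            rep_part, cyc_part = lab.split("_")
            out[lab] = (int(rep_part[3:]), int(cyc_part[3:]))
        return cls(out)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExperimentDesign":
        return cls(
            {
                row["sample"]: (int(row["replicate"]), int(row["cycle"]))
                for _, row in frame.iterrows()
            }
        )


def filter_low_count(count_table: pd.DataFrame, min_total: int = 5) -> pd.DataFrame:
    """Keep clones with at least ``min_total`` reads across the experiment."""
    return count_table.loc[count_table.sum(axis=1) >= min_total]


def estimate_size_factors(count_table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, the factor is the median over clones (nonzero in
    every sample) of count / geometric-mean(count across samples).  When
    no clone is nonzero everywhere, falls back to column-sum ratios.
    """
    x = count_table.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        lx = np.log(x[all_pos])
        log_gm = lx.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(lx - log_gm, axis=0))
    else:
        colsum = x.sum(axis=0)
        if (colsum <= 0).any():
            raise ValueError("cannot estimate size factors: empty sample column")
        factors = colsum
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=count_table.columns, name="size_factor")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _dispersion_trend(mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu over clones with informative estimates."""
    use = disp > _DISPERSION_FLOOR
    if use.sum() >= 10:
        X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
        coef, *_ = np.linalg.lstsq(X, disp[use], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
        trend = a0 + a1 / mu
    else:
        trend = np.full_like(mu, np.median(disp))
    return np.maximum(trend, _DISPERSION_FLOOR)


def fit_nb_and_test(
    count_table: pd.DataFrame,
    design: ExperimentDesign | None = None,
    size_factors: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-clone NB Wald test of the last-vs-first-cycle contrast.

    Returns a frame indexed by clone id with columns log2_fold_change,
    standard_error, p_value, p_adj, flag.  A cycle whose normalized mean
    is zero enters the contrast with a pseudo-mean of 0.5 normalized
    counts.
    """
    if design is None:
        design = ExperimentDesign.from_labels(count_table.columns)
    if size_factors is None:
        size_factors = estimate_size_factors(count_table)
    f = size_factors.reindex(count_table.columns).to_numpy(dtype=float)
    y = count_table.to_numpy(dtype=float) / f  # normalized counts

    cycles = design.cycles
    sample_cycle = np.array([design.cycle_of(s) for s in count_table.columns])
    groups = {c: np.nonzero(sample_cycle == c)[0] for c in cycles}

    # per-cycle normalized means and within-cycle moment dispersions
    q = np.column_stack([y[:, idx].mean(axis=1) for c, idx in groups.items()])
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    dof = 0
    for j, c in enumerate(cycles):
        idx = groups[c]
        n_c = idx.size
        if n_c < 2:
            continue
        resid = y[:, idx] - q[:, [j]]
        s2 = (resid**2).sum(axis=1) / (n_c - 1)
        # E[s2] ~ q * mean(1/f) + alpha q^2 under NB with size factors
        num += (n_c - 1) * (s2 - q[:, j] * np.mean(1.0 / f[idx]))
        den += (n_c - 1) * q[:, j] ** 2
        dof += n_c - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = np.where(den > 0, num / den, 0.0)
    disp_mom = np.maximum(disp_mom, _DISPERSION_FLOOR)

    mu = np.maximum(y.mean(axis=1), 1e-8)
    trend = _dispersion_trend(mu, disp_mom)
    disp = np.exp(0.5 * np.log(disp_mom) + 0.5 * np.log(trend))

    j1 = cycles.index(cycles[0])
    jL = cycles.index(cycles[-1])
    q1 = np.where(q[:, j1] > 0, q[:, j1], 0.5)
    qL = np.where(q[:, jL] > 0, q[:, jL], 0.5)
    beta = np.log2(qL) - np.log2(q1)

    def _var_log_q(qc: np.ndarray, idx: np.ndarray) -> np.ndarray:
        n_c = idx.size
        var_qhat = (qc * np.sum(1.0 / f[idx]) + disp * qc**2 * n_c) / n_c**2
        return var_qhat / qc**2

    se = np.sqrt(
        _var_log_q(q1, groups[cycles[0]]) + _var_log_q(qL, groups[cycles[-1]])
    ) / np.log(2.0)
    se = np.maximum(se, 1e-12)
    z = beta / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    p_adj = bh_adjust(p)

    flag = np.where(
        (p_adj < alpha) & (beta > 0),
        "POS",
        np.where((p_adj < alpha) & (beta < 0), "NEG", "NS"),
    )
    return pd.DataFrame(
        {
            "log2_fold_change": beta,
            "standard_error": se,
            "p_value": p,
            "p_adj": p_adj,
            "flag": flag,
        },
        index=count_table.index.rename("clone_id"),
    )


def run_experiment(
    count_table: pd.DataFrame,
    design: ExperimentDesign | None = None,
    min_total: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Filter low-count clones, normalize, test — one experiment end to end."""
    filtered = filter_low_count(count_table, min_total)
    if filtered.empty:
        raise ValueError("no clone passes the minimum count filter")
    return fit_nb_and_test(filtered, design, alpha=alpha)


def consensus_category(
    flags_by_experiment: pd.DataFrame,
    majority: int | None = None,
    n_experiments: int | None = None,
) -> pd.DataFrame:
    """Strict-majority consensus flag across experiments.

    ``flags_by_experiment`` holds one column per experiment with values in
    {POS, NEG, NS} or NaN where the clone was absent.  The majority
    threshold defaults to floor(n/2)+1 of the configured number of
    experiments (5 of 9 in a nine-experiment design); absent experiments
    still count toward the denominator.  Clones where no flag reaches the
    majority are UNASSIGNED.
    """
    n_exp = n_experiments or flags_by_experiment.shape[1]
    majority = majority or (n_exp // 2 + 1)
    counts = pd.DataFrame(
        {flag: (flags_by_experiment == flag).sum(axis=1) for flag in FLAGS}
    )
    # With a strict majority only one flag can qualify; with a lowered
    # threshold the most frequent qualifying flag wins, ties unassigned.
    best = counts.max(axis=1)
    tied = (counts.eq(best, axis=0)).sum(axis=1) > 1
    winner = counts.idxmax(axis=1)
    consensus = pd.Series("UNASSIGNED", index=flags_by_experiment.index)
    ok = (best >= majority) & ~tied
    consensus[ok] = winner[ok]
    out = flags_by_experiment.copy()
    out["consensus"] = consensus
    return out


def track_reference_clone(
    results_by_experiment: dict[str, pd.DataFrame], clone_id: str
) -> pd.DataFrame:
    """Per-experiment (log2FC, p_adj, flag) trace of one clone.

    Experiments where the clone was filtered out are marked absent.
    Raises if the clone appears in no experiment at all.
    """
    rows = []
    found = False
    for exp, res in results_by_experiment.items():
        if clone_id in res.index:
            found = True
            r = res.loc[clone_id]
            rows.append(
                {
                    "experiment": exp,
                    "present": True,
                    "log2_fold_change": r["log2_fold_change"],
                    "p_adj": r["p_adj"],
                    "flag": r["flag"],
                }
            )
        else:
            rows.append(
                {
                    "experiment": exp,
                    "present": False,
                    "log2_fold_change": np.nan,
                    "p_adj": np.nan,
                    "flag": None,
                }
            )
    if not found:
        raise KeyError(f"clone {clone_id!r} absent from every experiment")
    return pd.DataFrame(rows).set_index("experiment")
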
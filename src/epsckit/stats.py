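"""Group-comparison statistics and the cohort-level recovery harness.

Two-sample comparisons follow the conventional selection rule used for
this kind of cellular-physiology data: normality is assessed per group
with Shapiro-Wilk; when both groups pass, variance homogeneity (an F test
at the same level) chooses between Student's and Welch's t test, otherwise
the Mann-Whitney U test is used.  All tests are two-tailed.  Summaries are
mean +/- SD on the parametric branches and median +/- MAD (unscaled median
absolute deviation) otherwise.  No multiple-testing correction is applied;
reports state the number of comparisons made.

:func:`run_recovery` simulates whole WT/PL cohorts, runs every analysis
stage of the package on them, and compares the recovered metrics between
genotypes — the end-to-end check that the pipeline reproduces the encoded
effect pattern (elevated spontaneous and asynchronous release with intact
synchronous kinetics, release probability and total RRP).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import evoked, minis as minis_mod, synthgen
from .traceio import AnalysisConfig, ParameterError, timed

__all__ = [
    "GroupComparison",
    "RecoveryReport",
    "compare_groups",
    "summarize",
    "run_recovery",
    "type_one_error_rate",
    "RECOVERY_METRICS",
]


@dataclasses.dataclass
class GroupComparison:
    test_name: str      # {student_t, welch_t, mann_whitney_u}
    statistic: float
    p_value: float
    n1: int
    n2: int
    summary1: tuple     # (location, spread, label)
    summary2: tuple
    fold_change: float  # location2 / location1
    warnings: tuple = ()


def _mad(x: np.ndarray) -> float:
    """Unscaled median absolute deviation."""
    return float(np.median(np.abs(x - np.median(x))))


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False
    return float(sps.shapiro(x).pvalue) > alpha


def summarize(sample, alpha: float = 0.05):
    """(location, spread, label): mean +/- SD when Shapiro-Wilk does not
    reject normality, median +/- MAD otherwise.  Samples too small or too
    degenerate to test (n < 3 or constant) are summarized as mean +/- SD."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ParameterError("cannot summarize an empty sample")
    if x.size < 3 or np.ptp(x) == 0 or _shapiro_normal(x, alpha):
        return float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0, "mean±SD"
    return float(np.median(x)), _mad(x), "median±MAD"


def _mann_whitney(x1, x2):
    pooled = np.concatenate([x1, x2])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not ties and max(x1.size, x2.size) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(x1, x2, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(sample1, sample2, alpha: float = 0.05) -> GroupComparison:
    """Two-tailed comparison of two independent samples with automatic test
    selection (a pure function of the two samples and ``alpha``)."""
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if x1.size < 3 or x2.size < 3:
        raise ParameterError("compare_groups requires n >= 3 per group")
    warns = ()

    constant = np.ptp(x1) == 0 or np.ptp(x2) == 0
    if constant:
        warns = ("constant sample: normality stage bypassed",)
        warnings.warn(warns[0], stacklevel=2)
        normal = False
    else:
        normal = _shapiro_normal(x1, alpha) and _shapiro_normal(x2, alpha)

    if normal:
        v1, v2 = np.var(x1, ddof=1), np.var(x2, ddof=1)
        f = v1 / v2
        cdf = sps.f.cdf(f, x1.size - 1, x2.size - 1)
        p_var = 2.0 * min(cdf, 1.0 - cdf)
        equal_var = p_var > alpha
        res = sps.ttest_ind(x1, x2, equal_var=equal_var)
        name = "student_t" if equal_var else "welch_t"
        stat, p = float(res.statistic), float(res.pvalue)
        s1 = (float(np.mean(x1)), float(np.std(x1, ddof=1)), "mean±SD")
        s2 = (float(np.mean(x2)), float(np.std(x2, ddof=1)), "mean±SD")
        loc1, loc2 = s1[0], s2[0]
    else:
        stat, p = _mann_whitney(x1, x2)
        name = "mann_whitney_u"
        s1 = (float(np.median(x1)), _mad(x1), "median±MAD")
        s2 = (float(np.median(x2)), _mad(x2), "median±MAD")
        loc1, loc2 = s1[0], s2[0]

    fold = loc2 / loc1 if loc1 != 0 else float("nan")
    return GroupComparison(
        test_name=name, statistic=stat, p_value=p,
        n1=int(x1.size), n2=int(x2.size),
        summary1=s1, summary2=s2, fold_change=fold, warnings=warns,
    )


def type_one_error_rate(n_sims: int = 2000, n_per_group: int = 10,
                        alpha: float = 0.05, seed: int = 0) -> float:
    """False-positive rate of the full select-then-test procedure on normal
    null data (both groups drawn from the same normal distribution)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        a = rng.normal(0.0, 1.0, n_per_group)
        b = rng.normal(0.0, 1.0, n_per_group)
        if compare_groups(a, b, alpha).p_value < alpha:
            hits += 1
    return hits / n_sims


# ---------------------------------------------------------------------------
# cohort recovery harness
# ---------------------------------------------------------------------------

RECOVERY_METRICS = (
    "mini_frequency_hz",
    "mini_amplitude_pa",
    "epsc_amplitude_pa",
    "epsc_charge_pc",
    "tau_fast_ms",
    "tau_slow_ms",
    "async_fraction",
    "ppr",
    "train_async_fraction",
    "tail_tau_ms",
    "rrp_backextrap_pc",
    "recruitment_pc_per_s",
    "rrp_sucrose_pc",
)

_MINIS_DURATION = 60.0  # s of spontaneous recording per simulated cell


@dataclasses.dataclass
class RecoveryReport:
    """Per-metric recovery table and between-genotype comparisons."""

    table: pd.DataFrame                 # cell-level metric values
    comparisons: dict                   # metric -> GroupComparison
    truths: dict                        # metric -> {genotype: generator truth}
    summary: pd.DataFrame               # one row per metric
    n_comparisons: int = 0

    def direction(self, metric: str, alpha: float = 0.05) -> str:
        c = self.comparisons[metric]
        if c is None:
            return "n/a"
        if c.p_value >= alpha or np.isnan(c.fold_change):
            return "PL≈WT"
        return "PL>WT" if c.fold_change > 1 else "PL<WT"

    def indistinguishable(self, metric: str, fold_band: float = 0.15,
                          strong_alpha: float = 0.01) -> bool:
        """Equivalence-style check for metrics expected to be unchanged.

        Asserting the *absence* of an effect via ``p >= alpha`` alone is
        statistically unsound (a true null still fails alpha of the time);
        instead the recovered fold change must lie within ``fold_band`` of
        unity and there must be no strong evidence of a difference
        (``p >= strong_alpha``).
        """
        c = self.comparisons[metric]
        if c is None or np.isnan(c.fold_change):
            return False
        return (abs(c.fold_change - 1.0) <= fold_band
                and c.p_value >= strong_alpha)


def _cell_seed(seed: int, genotype: str, cell: int, stage: int) -> int:
    gcode = int.from_bytes(genotype.encode()[:4].ljust(4, b"\0"), "big")
    ss = np.random.SeedSequence([int(seed), gcode, int(cell), int(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _analyze_cell(genotype: str, cell: int, seed: int,
                  acfg: AnalysisConfig) -> dict:
    out = {"genotype": genotype, "cell": cell}
    base = synthgen.make_preset(genotype)

    # spontaneous minis
    cfg = base.replace(seed=_cell_seed(seed, genotype, cell, 0))
    tr, _ = synthgen.simulate_minis(cfg, _MINIS_DURATION)
    ev = minis_mod.detect_minis(evoked.preprocess(tr, acfg), acfg)
    st = minis_mod.mini_statistics(ev)
    out["mini_frequency_hz"] = st.frequency
    out["mini_amplitude_pa"] = st.mean_amplitude

    # single evoked EPSC
    cfg = base.replace(seed=_cell_seed(seed, genotype, cell, 1),
                       stimulus_times=synthgen.protocol_stimulus_times("epsc"))
    tr, _ = synthgen.simulate_evoked_epsc(cfg)
    m, fit = evoked.analyze_epsc(evoked.preprocess(tr, acfg), acfg)
    out["epsc_amplitude_pa"] = m.amplitude
    out["epsc_charge_pc"] = m.charge
    out["tau_fast_ms"] = fit.tau_fast
    out["tau_slow_ms"] = fit.tau_slow
    out["async_fraction"] = fit.async_fraction

    # paired pulses
    cfg = base.replace(seed=_cell_seed(seed, genotype, cell, 2),
                       stimulus_times=synthgen.protocol_stimulus_times("paired"))
    tr, _ = synthgen.simulate_train(cfg, duration=1.0)
    out["ppr"] = evoked.paired_pulse_ratio(evoked.preprocess(tr, acfg),
                                           config=acfg)

    # 20 Hz train
    cfg = base.replace(seed=_cell_seed(seed, genotype, cell, 3),
                       stimulus_times=synthgen.protocol_stimulus_times("train20"))
    tr, _ = synthgen.simulate_train(cfg)
    res20 = evoked.analyze_train(evoked.preprocess(tr, acfg), config=acfg)
    out["train_async_fraction"] = res20.train_async_fraction
    out["tail_tau_ms"] = res20.tail_tau

    # 40 Hz train -> back-extrapolated RRP
    cfg = base.replace(seed=_cell_seed(seed, genotype, cell, 4),
                       stimulus_times=synthgen.protocol_stimulus_times("train40"))
    tr, _ = synthgen.simulate_train(cfg)
    res40 = evoked.analyze_train(evoked.preprocess(tr, acfg), config=acfg)
    rrp = evoked.backextrapolate_rrp(res40, tr.stimulus_times, acfg)
    out["rrp_backextrap_pc"] = rrp.rrp_charge
    out["recruitment_pc_per_s"] = rrp.recruitment_rate

    # sucrose RRP
    cfg = base.replace(seed=_cell_seed(seed, genotype, cell, 5))
    window = (0.5, 2.5)
    tr, _ = synthgen.simulate_sucrose(cfg, window)
    suc = evoked.estimate_rrp_sucrose(evoked.preprocess(tr, acfg), window, acfg)
    out["rrp_sucrose_pc"] = suc.rrp_charge
    return out


def _generator_truths(genotype: str) -> dict:
    cfg = synthgen.make_preset(genotype)
    qc = cfg.mean_quantal_charge
    total = cfg.n_sync + cfg.async_count_mean
    return {
        "mini_frequency_hz": cfg.mini_rate,
        "mini_amplitude_pa": cfg.quantal_amplitude,
        "epsc_amplitude_pa": float("nan"),
        "epsc_charge_pc": total * qc,
        "tau_fast_ms": cfg.tau_decay,
        "tau_slow_ms": cfg.tau_async,
        "async_fraction": cfg.async_count_mean / total,
        "ppr": 1.0 - cfg.release_fraction,
        "train_async_fraction": float("nan"),
        "tail_tau_ms": cfg.tau_async,
        "rrp_backextrap_pc": cfg.pool_size * qc,
        "recruitment_pc_per_s": cfg.recruitment_rate * qc,
        "rrp_sucrose_pc": cfg.pool_size * qc,
    }


def run_recovery(genotypes=("WT", "PL"), n_cells: int = 30, seed: int = 0,
                 alpha: float = 0.05,
                 config: AnalysisConfig | None = None) -> RecoveryReport:
    """Simulate ``n_cells`` per genotype across all protocols, run every
    analysis stage, and compare the recovered metrics between genotypes."""
    if n_cells < 10:
        raise ParameterError("run_recovery requires n_cells >= 10 per genotype")
    acfg = config or AnalysisConfig(alpha=alpha)
    rows = []
    for g in genotypes:
        with timed(f"recovery cohort {g} (n={n_cells})"):
            for c in range(n_cells):
                rows.append(_analyze_cell(g, c, seed, acfg))
    table = pd.DataFrame(rows)

    comparisons, summary_rows = {}, []
    g1, g2 = genotypes[0], genotypes[1] if len(genotypes) > 1 else genotypes[0]
    truths = {m: {g: _generator_truths(g)[m] for g in genotypes}
              for m in RECOVERY_METRICS}
    for m in RECOVERY_METRICS:
        a = table.loc[table.genotype == g1, m].dropna().to_numpy()
        b = table.loc[table.genotype == g2, m].dropna().to_numpy()
        if min(a.size, b.size) < 3:
            comparisons[m] = None
            continue
        cmp_ = compare_groups(a, b, alpha)
        comparisons[m] = cmp_
        t1, t2 = truths[m][g1], truths[m][g2]
        rec1 = float(np.mean(a)) if a.size else float("nan")
        rec2 = float(np.mean(b)) if b.size else float("nan")
        summary_rows.append({
            "metric": m,
            f"true_{g1}": t1, f"recovered_{g1}": rec1,
            f"rel_err_{g1}": abs(rec1 - t1) / abs(t1) if t1 else float("nan"),
            f"true_{g2}": t2, f"recovered_{g2}": rec2,
            f"rel_err_{g2}": abs(rec2 - t2) / abs(t2) if t2 else float("nan"),
            "test": cmp_.test_name, "statistic": cmp_.statistic,
            "p": cmp_.p_value, "fold_change": cmp_.fold_change,
        })
    summary = pd.DataFrame(summary_rows)
    report = RecoveryReport(table=table, comparisons=comparisons,
                            truths=truths, summary=summary,
                            n_comparisons=len(RECOVERY_METRICS))
    return report
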
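"""Synthetic two-group cosinor data and simulation experiments.

The generator draws data exactly from the Gaussian cosinor model

    Y = A cos(2 pi / P (t - phi)) + M + eps,  eps ~ N(0, sigma^2),

per group and per gene, so every downstream test is exercised under its own
model assumptions.  Experiments built on the generator quantify type-I
error (:func:`calibration_experiment`), statistical power (same function on
an alternative scenario) and estimator quality (:func:`recovery_experiment`).

Seeds are explicit everywhere; no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .classify import ssms_classify
from .cosinor import fit_cosinor, rhythm_test
from .dataset import RhythmDataset
from .drtests import fitness_test, global_param_test, posthoc_param_test

__all__ = [
    "GroupParams",
    "SimScenario",
    "simulate_dataset",
    "simulate_tor_mixture",
    "calibration_experiment",
    "recovery_experiment",
    "ssms_error_experiment",
    "CalibrationResult",
]


@dataclass(frozen=True)
class GroupParams:
    """True cosinor parameters for one group."""

    amplitude: float = 0.0
    phase: float = 0.0
    mesor: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")

    @property
    def snr(self) -> float:
        if self.sigma == 0:
            return math.inf if self.amplitude > 0 else 0.0
        return self.amplitude / self.sigma

    def curve(self, t: np.ndarray, period: float) -> np.ndarray:
        w = 2.0 * math.pi / period
        return self.amplitude * np.cos(w * (np.asarray(t, float) - self.phase)) + self.mesor


@dataclass(frozen=True)
class SimScenario:
    """A two-group simulation scenario.

    ``design`` is ``"even"`` (evenly spaced over one period, the common
    circadian collection design), ``"uniform"`` (times drawn uniformly on
    ``[0, P)`` per gene), or ``"explicit"`` with ``times`` giving the shared
    per-group time list.
    """

    group_i: GroupParams = field(default_factory=GroupParams)
    group_ii: GroupParams = field(default_factory=GroupParams)
    n_per_group: int = 24
    design: str = "even"
    times: tuple | None = None
    period: float = 24.0
    n_genes: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 5:
            raise ValueError("n_per_group must be at least 5")
        if self.design not in {"even", "uniform", "explicit"}:
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "explicit":
            if self.times is None or len(self.times) != self.n_per_group:
                raise ValueError("explicit design requires times of length n_per_group")
            t = np.mod(np.asarray(self.times, float), self.period)
            if np.unique(np.round(t, 9)).size < 3:
                raise ValueError("explicit time design is degenerate (< 3 distinct times)")
        if not self.period > 0:
            raise ValueError("period must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be at least 1")

    def sample_times(self, rng: np.random.Generator) -> np.ndarray:
        if self.design == "even":
            return np.arange(self.n_per_group) * (self.period / self.n_per_group)
        if self.design == "uniform":
            return rng.uniform(0.0, self.period, self.n_per_group)
        return np.asarray(self.times, dtype=float)

    def true_category(self) -> str:
        rhy_i = self.group_i.amplitude > 0
        rhy_ii = self.group_ii.amplitude > 0
        if rhy_i and rhy_ii:
            return "RhyBoth"
        if rhy_i:
            return "RhyI"
        if rhy_ii:
            return "RhyII"
        return "Arrhy"


def _truth_row(gene: str, gi: GroupParams, gii: GroupParams, category: str) -> dict:
    return {
        "gene": gene,
        "A_I": gi.amplitude, "phi_I": gi.phase, "M_I": gi.mesor, "sigma_I": gi.sigma,
        "A_II": gii.amplitude, "phi_II": gii.phase, "M_II": gii.mesor,
        "sigma_II": gii.sigma, "category": category,
    }


def simulate_dataset(scenario: SimScenario) -> tuple[RhythmDataset, pd.DataFrame]:
    """Generate a dataset where every gene shares the scenario's parameters.

    Returns the dataset plus a per-gene truth table (true parameters and
    true TOR category).  Bit-reproducible given ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_per_group
    G = scenario.n_genes
    t_I = scenario.sample_times(rng)
    t_II = scenario.sample_times(rng)
    mean_I = scenario.group_i.curve(t_I, scenario.period)
    mean_II = scenario.group_ii.curve(t_II, scenario.period)
    vals = np.empty((G, 2 * n))
    vals[:, :n] = mean_I + rng.normal(0.0, scenario.group_i.sigma, (G, n))
    vals[:, n:] = mean_II + rng.normal(0.0, scenario.group_ii.sigma, (G, n))
    genes = [f"g{i}" for i in range(G)]
    ds = RhythmDataset(
        values=vals,
        gene_ids=genes,
        sample_ids=[f"I_s{i}" for i in range(n)] + [f"II_s{i}" for i in range(n)],
        time=np.concatenate([t_I, t_II]),
        group=np.array(["I"] * n + ["II"] * n, dtype=object),
        period=scenario.period,
    )
    cat = scenario.true_category()
    truth = pd.DataFrame(
        [_truth_row(g, scenario.group_i, scenario.group_ii, cat) for g in genes]
    )
    return ds, truth


def simulate_tor_mixture(
    n_rhyboth: int = 30,
    n_rhyi: int = 20,
    n_rhyii: int = 20,
    n_arrhy: int = 30,
    snr: float = 3.0,
    sigma: float = 1.0,
    mesor: float = 10.0,
    n_per_group: int = 24,
    period: float = 24.0,
    seed: int = 0,
) -> tuple[RhythmDataset, pd.DataFrame]:
    """Mixed-truth dataset with genes drawn from all four TOR categories.

    Rhythmic genes get amplitude ``snr * sigma`` and a phase drawn uniformly
    on ``[0, P)`` per gene and group; both groups share the even design over
    one period.  Used as the end-to-end pipeline fixture and by the
    classification error experiments.
    """
    rng = np.random.default_rng(seed)
    n = n_per_group
    t = np.arange(n) * (period / n)
    A = snr * sigma
    specs: list[tuple[str, bool, bool]] = (
        [("RhyBoth", True, True)] * n_rhyboth
        + [("RhyI", True, False)] * n_rhyi
        + [("RhyII", False, True)] * n_rhyii
        + [("Arrhy", False, False)] * n_arrhy
    )
    G = len(specs)
    if G == 0:
        raise ValueError("at least one gene is required")
    vals = np.empty((G, 2 * n))
    rows = []
    for i, (cat, rhy_i, rhy_ii) in enumerate(specs):
        gi = GroupParams(
            amplitude=A if rhy_i else 0.0,
            phase=float(rng.uniform(0, period)) if rhy_i else 0.0,
            mesor=mesor, sigma=sigma,
        )
        gii = GroupParams(
            amplitude=A if rhy_ii else 0.0,
            phase=float(rng.uniform(0, period)) if rhy_ii else 0.0,
            mesor=mesor, sigma=sigma,
        )
        vals[i, :n] = gi.curve(t, period) + rng.normal(0.0, sigma, n)
        vals[i, n:] = gii.curve(t, period) + rng.normal(0.0, sigma, n)
        rows.append(_truth_row(f"g{i:03d}", gi, gii, cat))
    ds = RhythmDataset(
        values=vals,
        gene_ids=[r["gene"] for r in rows],
        sample_ids=[f"I_s{i}" for i in range(n)] + [f"II_s{i}" for i in range(n)],
        time=np.concatenate([t, t]),
        group=np.array(["I"] * n + ["II"] * n, dtype=object),
        period=period,
    )
    return ds, pd.DataFrame(rows)


@dataclass(frozen=True)
class CalibrationResult:
    """Empirical rejection rate with its exact binomial confidence interval."""

    test: str
    n_reps: int
    alpha: float
    n_reject: int
    rate: float
    ci_low: float
    ci_high: float
    p_values: np.ndarray

    def within_envelope(self, target: float) -> bool:
        return self.ci_low <= target <= self.ci_high


def _rep_pvalue(test: str, scenario: SimScenario, rng: np.random.Generator,
                alpha: float) -> float:
    """One simulated replicate's p-value (or family-rejection surrogate)."""
    n = scenario.n_per_group
    t_I = scenario.sample_times(rng)
    t_II = scenario.sample_times(rng)
    y_I = scenario.group_i.curve(t_I, scenario.period) + rng.normal(
        0.0, scenario.group_i.sigma, n)
    y_II = scenario.group_ii.curve(t_II, scenario.period) + rng.normal(
        0.0, scenario.group_ii.sigma, n)
    if test in {"rhythm_F", "rhythm_LRT"}:
        _, _, p = rhythm_test(y_I, t_I, scenario.period,
                              method=test.split("_")[1])
        return p
    if test == "fitness":
        return fitness_test(y_I, t_I, y_II, t_II, scenario.period).p_value
    if test == "global_phiA":
        return global_param_test(y_I, t_I, y_II, t_II, scenario.period,
                                 params=("phase", "amplitude")).p_value
    if test == "global_phiAM":
        return global_param_test(y_I, t_I, y_II, t_II, scenario.period,
                                 params=("phase", "amplitude", "mesor")).p_value
    if test == "posthoc_family":
        glob = global_param_test(y_I, t_I, y_II, t_II, scenario.period,
                                 params=("phase", "amplitude", "mesor"))
        if not glob.p_value <= alpha:
            return 1.0  # gate closed: no post-hoc rejection possible
        p_min = min(
            posthoc_param_test(y_I, t_I, y_II, t_II, scenario.period, p).p_value
            for p in ("phase", "amplitude", "mesor")
        )
        return p_min
    if test.startswith("posthoc_"):
        param = test.split("_", 1)[1]
        return posthoc_param_test(y_I, t_I, y_II, t_II, scenario.period,
                                  param).p_value
    raise ValueError(f"unknown test {test!r}")


_NULL_CHECKS = {
    "rhythm_F": lambda s: s.group_i.amplitude == 0.0,
    "rhythm_LRT": lambda s: s.group_i.amplitude == 0.0,
    "fitness": lambda s: math.isclose(s.group_i.snr, s.group_ii.snr),
    "global_phiA": lambda s: (
        s.group_i.amplitude == s.group_ii.amplitude
        and s.group_i.phase == s.group_ii.phase
    ),
    "global_phiAM": lambda s: (
        s.group_i.amplitude == s.group_ii.amplitude
        and s.group_i.phase == s.group_ii.phase
        and s.group_i.mesor == s.group_ii.mesor
    ),
    "posthoc_family": lambda s: s.group_i == s.group_ii,
    "posthoc_phase": lambda s: s.group_i.phase == s.group_ii.phase,
    "posthoc_amplitude": lambda s: s.group_i.amplitude == s.group_ii.amplitude,
    "posthoc_mesor": lambda s: s.group_i.mesor == s.group_ii.mesor,
}


def calibration_experiment(
    test: str,
    scenario: SimScenario,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    require_null: bool = True,
) -> CalibrationResult:
    """Monte-Carlo rejection rate of a named test under a scenario.

    Parameters
    ----------
    test : str
        One of ``rhythm_F, rhythm_LRT, fitness, global_phiA, global_phiAM,
        posthoc_phase, posthoc_amplitude, posthoc_mesor, posthoc_family``.
        ``posthoc_family`` counts a replicate as rejected when the global
        (phase, amplitude, mesor) gate opens *and* any post-hoc test
        rejects — the per-biomarker family error of the two-stage design.
    scenario : SimScenario
        Data-generating truth for every replicate (fresh noise each rep).
    require_null : bool
        When True (default) the scenario must satisfy the named test's null
        hypothesis; pass False to measure power under an alternative.

    Returns
    -------
    CalibrationResult
        Rejection rate at ``alpha`` with a 99% exact (Clopper-Pearson)
        binomial interval and the per-replicate p-values.
    """
    if test not in _NULL_CHECKS:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(_NULL_CHECKS)}")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if require_null and not _NULL_CHECKS[test](scenario):
        raise ValueError(
            f"scenario violates the null hypothesis of test {test!r} "
            "(pass require_null=False to measure power)"
        )
    rng = np.random.default_rng(seed)
    pvals = np.array(
        [_rep_pvalue(test, scenario, rng, alpha) for _ in range(n_reps)]
    )
    n_reject = int(np.sum(pvals <= alpha))
    ci = binomtest(n_reject, n_reps).proportion_ci(confidence_level=0.99)
    return CalibrationResult(
        test=test, n_reps=n_reps, alpha=alpha, n_reject=n_reject,
        rate=n_reject / n_reps, ci_low=float(ci.low), ci_high=float(ci.high),
        p_values=pvals,
    )


def recovery_experiment(
    scenario: SimScenario, n_reps: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Bias and RMSE of the cosinor MLE across simulated replicates.

    Fits group I of the scenario in each replicate and summarizes the
    estimation error of amplitude, phase (circular, wrapped to
    ``(-P/2, P/2]``), MESOR and residual SD.

    Raises
    ------
    ValueError
        For an arrhythmic scenario (phase unidentifiable at A = 0).
    """
    g = scenario.group_i
    if g.amplitude <= 0:
        raise ValueError("recovery_experiment needs a rhythmic scenario (A > 0)")
    rng = np.random.default_rng(seed)
    P = scenario.period
    half = P / 2.0
    errs = {"amplitude": [], "phase": [], "mesor": [], "sigma": []}
    for _ in range(n_reps):
        t = scenario.sample_times(rng)
        y = g.curve(t, P) + rng.normal(0.0, g.sigma, scenario.n_per_group)
        fit = fit_cosinor(y, t, P)
        errs["amplitude"].append(fit.amplitude - g.amplitude)
        dphi = (fit.phase - g.phase) % P
        if dphi > half:
            dphi -= P
        errs["phase"].append(dphi)
        errs["mesor"].append(fit.mesor - g.mesor)
        errs["sigma"].append(fit.sigma - g.sigma)
    rows = []
    for name, e in errs.items():
        e = np.asarray(e)
        rows.append(
            {"parameter": name, "bias": float(e.mean()),
             "rmse": float(np.sqrt(np.mean(e**2)))}
        )
    return pd.DataFrame(rows)


def ssms_error_experiment(
    truth: str,
    n_genes: int = 2000,
    snr: float = 3.0,
    level: float = 0.05,
    n_per_group: int = 24,
    period: float = 24.0,
    seed: int = 0,
) -> CalibrationResult:
    """Monte-Carlo misclassification rate of the SSMS categorizer.

    ``truth="Arrhy"`` measures the rate of calling a doubly-arrhythmic gene
    anything else; ``truth="RhyI"`` the rate of calling a gene rhythmic only
    in group I (at the given SNR) RhyBoth.  Classification uses raw-alpha
    thresholds (``adjust="none"``) so the per-gene rates are interpretable.
    """
    if truth not in {"Arrhy", "RhyI"}:
        raise ValueError("truth must be 'Arrhy' or 'RhyI'")
    rng = np.random.default_rng(seed)
    n = n_per_group
    t = np.arange(n) * (period / n)
    A_I = snr if truth == "RhyI" else 0.0
    gi = GroupParams(amplitude=A_I, phase=0.0, mesor=0.0, sigma=1.0)
    gii = GroupParams(amplitude=0.0, phase=0.0, mesor=0.0, sigma=1.0)
    p_I = np.empty(n_genes)
    p_II = np.empty(n_genes)
    for i in range(n_genes):
        y_I = gi.curve(t, period) + rng.normal(0.0, 1.0, n)
        y_II = gii.curve(t, period) + rng.normal(0.0, 1.0, n)
        _, _, p_I[i] = rhythm_test(y_I, t, period, method="F")
        _, _, p_II[i] = rhythm_test(y_II, t, period, method="F")
    tor = ssms_classify(p_I, p_II, level=level, adjust="none")
    if truth == "Arrhy":
        n_err = int((tor["category"] != "Arrhy").sum())
        name = "ssms_arrhy_error"
    else:
        n_err = int((tor["category"] == "RhyBoth").sum())
        name = "ssms_rhyboth_error"
    ci = binomtest(n_err, n_genes).proportion_ci(confidence_level=0.99)
    return CalibrationResult(
        test=name, n_reps=n_genes, alpha=level, n_reject=n_err,
        rate=n_err / n_genes, ci_low=float(ci.low), ci_high=float(ci.high),
        p_values=tor["p_stage1"].to_numpy(),
    )
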
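"""Synthetic paired RT-qPCR / IHC / FISH cohorts.

Generates cohorts with the statistical structure a real FFPE breast-cancer
validation series displays, so the whole call -> score -> concordance
pipeline is testable without patient data:

* ER/PR: three latent expression classes (negative, low-positive, positive);
  delta-Ct drawn from a Gaussian mixture whose low-positive component sits at
  the assay cutoff, and percent staining obtained through a monotone logistic
  link of the true delta-Ct plus logit-scale noise — so the 1-9% low-positive
  stratum concentrates near the cutoff and supplies most discordance;
* HER2: a latent amplified state; IHC category via an ordered cut of a noisy
  delta-Ct latent (2+ equivocals straddle the cutoff) and a HER2/CEP17 FISH
  ratio drawn lognormally with a positive delta-Ct slope within each state;
* Ki67: a single broad latent continuum (no separated classes); the high/low
  truth label thresholds the latent expression at the assay cutoff;
* reference gene: a two-group block-age mixture; old blocks have elevated
  CYFIP1 Ct, driving a ~4% cartridge-invalid rate and the indeterminate
  below-cutoff PGR/MKI67 calls of input-limited samples.

Observed target Ct is reconstructed as Ct(CYFIP1) - observed dCt, where the
observed dCt adds instrument noise to the latent dCt; Ct values beyond the
amplification ceiling are recorded as absent.  The same spec and seed always
reproduce the cohort bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import ANALYTES, AssayConfig, call_table
from .ihc import DEFAULT_RULES, score_table
from .concordance import build_table, agreement_stats, optimize_cutoff, roc

__all__ = [
    "HormoneReceptorParams",
    "Her2Params",
    "Ki67Params",
    "ReferenceGeneParams",
    "CohortSpec",
    "SimulatedCohort",
    "generate",
    "roundtrip_check",
    "RecoveryReport",
]


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class HormoneReceptorParams:
    """ER/PR generator: latent class mixture and the dCt -> %staining link.

    ``link_mid``/``link_scale`` place the logistic link so that the 1%
    positivity boundary falls exactly at ``boundary_dct`` (the assay cutoff):
    link_mid = boundary_dct - link_scale * logit(0.01).
    """

    p_positive: float
    p_low_positive: float
    pos_mean: float
    pos_sd: float
    low_mean: float
    low_sd: float
    neg_mean: float
    neg_sd: float
    boundary_dct: float
    link_scale: float
    link_noise_sd: float
    assay_noise_sd: float = 0.3

    @property
    def link_mid(self) -> float:
        return self.boundary_dct - self.link_scale * _logit(0.01)

    def __post_init__(self):
        if not 0 <= self.p_positive + self.p_low_positive <= 1:
            raise ValueError("class probabilities must sum within [0, 1]")
        for name in ("pos_sd", "low_sd", "neg_sd", "link_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Her2Params:
    """HER2 generator: amplified-state mixture, ordered IHC cut, FISH link."""

    p_amplified: float = 0.14
    amp_mean: float = 2.5
    amp_sd: float = 1.3
    normal_mean: float = -4.0
    normal_sd: float = 1.8
    ihc_latent_noise_sd: float = 1.0
    # ordered cutpoints on (dct + noise) separating IHC 0 | 1+ | 2+ | 3+
    ihc_cutpoints: tuple[float, float, float] = (-4.5, -2.2, 1.6)
    ratio_log_intercept_amp: float = math.log(4.2)
    ratio_log_intercept_normal: float = math.log(1.25)
    ratio_dct_slope: float = 0.08
    ratio_log_sd_amp: float = 0.25
    ratio_log_sd_normal: float = 0.18
    assay_noise_sd: float = 0.3

    def __post_init__(self):
        if not 0 <= self.p_amplified <= 1:
            raise ValueError("p_amplified must be a probability")
        if list(self.ihc_cutpoints) != sorted(self.ihc_cutpoints):
            raise ValueError("ihc_cutpoints must be increasing")


@dataclass(frozen=True)
class Ki67Params:
    """Ki67 generator: one broad latent continuum, no separated classes.

    The truth label thresholds the latent expression at ``boundary_dct``; the
    link places 20% staining at that same latent value, so IHC and assay
    boundaries coincide in expectation.
    """

    latent_mean: float = -4.1
    latent_sd: float = 2.2
    boundary_dct: float = -4.0
    link_scale: float = 1.5
    link_noise_sd: float = 1.0
    assay_noise_sd: float = 1.3

    @property
    def link_mid(self) -> float:
        return self.boundary_dct - self.link_scale * _logit(0.20)

    def __post_init__(self):
        for name in ("latent_sd", "link_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ReferenceGeneParams:
    """CYFIP1 Ct: block-age mixture driving invalidity and input gating."""

    old_block_fraction: float = 0.15
    new_mean: float = 28.0
    new_sd: float = 1.5
    old_mean: float = 33.8
    old_sd: float = 2.0
    absent_above: float = 40.0

    def __post_init__(self):
        if not 0 <= self.old_block_fraction <= 1:
            raise ValueError("old_block_fraction must be a probability")

    def marginal_invalid_probability(self, valid_max: float = 35.0) -> float:
        from scipy.stats import norm

        p_old = self.old_block_fraction
        return float(
            p_old * norm.sf(valid_max, self.old_mean, self.old_sd)
            + (1 - p_old) * norm.sf(valid_max, self.new_mean, self.new_sd)
        )


def _default_er() -> HormoneReceptorParams:
    return HormoneReceptorParams(
        p_positive=0.79, p_low_positive=0.05,
        pos_mean=4.5, pos_sd=1.5, low_mean=-1.0, low_sd=0.9,
        neg_mean=-5.5, neg_sd=1.5,
        boundary_dct=-1.0, link_scale=0.9, link_noise_sd=0.7,
    )


def _default_pr() -> HormoneReceptorParams:
    return HormoneReceptorParams(
        p_positive=0.64, p_low_positive=0.12,
        pos_mean=1.0, pos_sd=2.0, low_mean=-3.5, low_sd=1.2,
        neg_mean=-7.0, neg_sd=2.0,
        boundary_dct=-3.5, link_scale=1.1, link_noise_sd=1.7,
        assay_noise_sd=0.5,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Everything the generator needs; same spec + seed => identical cohort."""

    n_samples: int = 523
    seed: int = 0
    er: HormoneReceptorParams = field(default_factory=_default_er)
    pr: HormoneReceptorParams = field(default_factory=_default_pr)
    her2: Her2Params = field(default_factory=Her2Params)
    ki67: Ki67Params = field(default_factory=Ki67Params)
    cyfip1: ReferenceGeneParams = field(default_factory=ReferenceGeneParams)
    target_ct_absent_above: float = 42.0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass
class SimulatedCohort:
    """Generated tables: Ct panels, IHC, FISH, and the latent truth."""

    panels: pd.DataFrame
    ihc: pd.DataFrame
    fish: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("panels", self.panels), ("ihc", self.ihc),
            ("fish", self.fish), ("truth", self.truth),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.6g")
            paths[name] = p
        return paths


def _draw_hr(rng, n, p: HormoneReceptorParams):
    """Latent class, true dCt, observed dCt and percent staining for ER/PR."""
    u = rng.random(n)
    state = np.where(
        u < p.p_positive, "positive",
        np.where(u < p.p_positive + p.p_low_positive, "low_positive", "negative"),
    )
    mean = np.select(
        [state == "positive", state == "low_positive"], [p.pos_mean, p.low_mean], p.neg_mean
    )
    sd = np.select(
        [state == "positive", state == "low_positive"], [p.pos_sd, p.low_sd], p.neg_sd
    )
    dct_true = rng.normal(mean, sd)
    dct_obs = dct_true + rng.normal(0.0, p.assay_noise_sd, n) if p.assay_noise_sd > 0 else dct_true.copy()
    logit = (dct_true - p.link_mid) / p.link_scale
    if p.link_noise_sd > 0:
        logit = logit + rng.normal(0.0, p.link_noise_sd, n)
    percent = np.round(100.0 * _logistic(logit), 1)
    return state, dct_true, dct_obs, percent


def _intensity_split(rng, percent, dct):
    """Split percent staining into 1+/2+/3+ fractions, skewed to 3+ at high dCt."""
    n = percent.size
    alpha3 = 1.0 + np.clip(dct, 0.0, 8.0)
    alphas = np.column_stack([np.full(n, 2.0), np.full(n, 3.0), alpha3])
    g = rng.standard_gamma(alphas)
    w = g / g.sum(axis=1, keepdims=True)
    f1 = np.round(w[:, 0] * percent, 1)
    f2 = np.round(w[:, 1] * percent, 1)
    f3 = np.round(np.maximum(percent - f1 - f2, 0.0), 1)  # residual: sum never exceeds percent
    return f1, f2, f3


def generate(spec: CohortSpec) -> SimulatedCohort:
    """Draw one cohort.  See the module docstring for the generative model."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = np.array([f"S{i + 1:04d}" for i in range(n)])

    # reference gene / block age
    old_block = rng.random(n) < spec.cyfip1.old_block_fraction
    ct_cyfip1 = np.where(
        old_block,
        rng.normal(spec.cyfip1.old_mean, spec.cyfip1.old_sd, n),
        rng.normal(spec.cyfip1.new_mean, spec.cyfip1.new_sd, n),
    )
    ct_cyfip1 = np.maximum(ct_cyfip1, 20.0)

    er_state, er_true, er_obs, er_pct = _draw_hr(rng, n, spec.er)
    pr_state, pr_true, pr_obs, pr_pct = _draw_hr(rng, n, spec.pr)
    er_p1, er_p2, er_p3 = _intensity_split(rng, er_pct, er_true)
    pr_p1, pr_p2, pr_p3 = _intensity_split(rng, pr_pct, pr_true)

    # HER2
    h = spec.her2
    amplified = rng.random(n) < h.p_amplified
    her2_true = np.where(
        amplified, rng.normal(h.amp_mean, h.amp_sd, n), rng.normal(h.normal_mean, h.normal_sd, n)
    )
    her2_obs = her2_true + rng.normal(0.0, h.assay_noise_sd, n)
    ihc_latent = her2_true + rng.normal(0.0, h.ihc_latent_noise_sd, n)
    c1, c2, c3 = h.ihc_cutpoints
    her2_cat = np.select(
        [ihc_latent < c1, ihc_latent < c2, ihc_latent < c3], ["0", "1+", "2+"], "3+"
    )
    state_mean = np.where(amplified, h.amp_mean, h.normal_mean)
    log_ratio = (
        np.where(amplified, h.ratio_log_intercept_amp, h.ratio_log_intercept_normal)
        + h.ratio_dct_slope * (her2_true - state_mean)
        + rng.normal(0.0, 1.0, n) * np.where(amplified, h.ratio_log_sd_amp, h.ratio_log_sd_normal)
    )
    fish_ratio = np.round(np.exp(log_ratio), 2)

    # Ki67 continuum
    k = spec.ki67
    ki_latent = rng.normal(k.latent_mean, k.latent_sd, n)
    ki_obs = ki_latent + rng.normal(0.0, k.assay_noise_sd, n)
    ki_logit = (ki_latent - k.link_mid) / k.link_scale
    if k.link_noise_sd > 0:
        ki_logit = ki_logit + rng.normal(0.0, k.link_noise_sd, n)
    ki_pct = np.round(100.0 * _logistic(ki_logit), 1)

    # reconstruct target Ct; beyond the amplification ceiling means absent
    def target_ct(dct_obs):
        ct = ct_cyfip1 - dct_obs
        return np.where(ct > spec.target_ct_absent_above, np.nan, np.round(ct, 2))

    panels = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "ct_esr1": target_ct(er_obs),
            "ct_pgr": target_ct(pr_obs),
            "ct_erbb2": target_ct(her2_obs),
            "ct_mki67": target_ct(ki_obs),
            "ct_cyfip1": np.where(ct_cyfip1 > spec.cyfip1.absent_above, np.nan, np.round(ct_cyfip1, 2)),
        }
    )

    def marker_rows(marker, pct=None, p1=None, p2=None, p3=None, cat=None):
        return pd.DataFrame(
            {
                "sample_id": sample_ids,
                "marker": marker,
                "percent_positive": pct if pct is not None else np.nan,
                "pct_1plus": p1 if p1 is not None else np.nan,
                "pct_2plus": p2 if p2 is not None else np.nan,
                "pct_3plus": p3 if p3 is not None else np.nan,
                "her2_category": cat if cat is not None else None,
            }
        )

    ihc = pd.concat(
        [
            marker_rows("ER", er_pct, er_p1, er_p2, er_p3),
            marker_rows("PR", pr_pct, pr_p1, pr_p2, pr_p3),
            marker_rows("HER2", cat=her2_cat),
            marker_rows("Ki67", ki_pct),
        ],
        ignore_index=True,
    )
    fish = pd.DataFrame({"sample_id": sample_ids, "her2_cep17_ratio": fish_ratio})

    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "old_block": old_block,
            "ct_cyfip1_true": np.round(ct_cyfip1, 4),
            "er_state": er_state,
            "pr_state": pr_state,
            "her2_amplified": amplified,
            "dct_true_esr1": np.round(er_true, 4),
            "dct_true_pgr": np.round(pr_true, 4),
            "dct_true_erbb2": np.round(her2_true, 4),
            "dct_true_mki67": np.round(ki_latent, 4),
            "ki67_high_true": ki_latent >= k.boundary_dct,
        }
    )
    return SimulatedCohort(panels=panels, ihc=ihc, fish=fish, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# round-trip: run the full pipeline on a generated cohort and report recovery

PRIMARY_RULES = {
    "ESR1": "er_1pct",
    "PGR": "pr_1pct",
    "ERBB2": "her2_ihc_plus_fish",
    "MKI67": "ki67_20pct",
}


@dataclass
class AnalyteRecovery:
    auc: float
    cutoff_estimate: float
    cutoff_error: float
    opa: float
    truth_agreement: float
    n_used: int


@dataclass
class RecoveryReport:
    per_analyte: dict[str, AnalyteRecovery]

    @property
    def auc_ordering_ok(self) -> bool:
        """ESR1 and ERBB2 above PGR, PGR above MKI67 (the expected ordering)."""
        a = {k: v.auc for k, v in self.per_analyte.items()}
        if any(math.isnan(v) for v in a.values()):
            return False
        return (
            a["ESR1"] > a["PGR"] and a["ERBB2"] > a["PGR"] and a["PGR"] > a["MKI67"]
        )


def analyte_scores_and_labels(
    cohort: SimulatedCohort,
    analyte: str,
    assay: AssayConfig | None = None,
    calls: pd.DataFrame | None = None,
    scored: pd.DataFrame | None = None,
):
    """Paired (dCt score, binary reference label) arrays for one analyte.

    Uses every sample with a valid cartridge, a finite observed dCt and a
    binary reference status under the analyte's primary comparator rule.
    """
    assay = assay or AssayConfig()
    if calls is None:
        calls = call_table(cohort.panels, assay)
    if scored is None:
        scored = score_table(cohort.ihc, cohort.fish, DEFAULT_RULES)
    sub = calls[(calls["analyte"] == analyte) & (calls["status"] != "INVALID")]
    sub = sub[np.isfinite(sub["dct"].to_numpy(float))]
    ref = scored[scored["rule_id"] == PRIMARY_RULES[analyte]]
    ref = ref[ref["status"].isin(["POSITIVE", "NEGATIVE", "HIGH", "LOW"])]
    merged = sub.merge(ref[["sample_id", "status"]], on="sample_id", suffixes=("", "_ref"))
    scores = merged["dct"].to_numpy(float)
    labels = merged["status_ref"].isin(["POSITIVE", "HIGH"]).to_numpy()
    return scores, labels


def roundtrip_check(spec: CohortSpec, assay: AssayConfig | None = None) -> RecoveryReport:
    """Generate a cohort, run the full pipeline, and measure recovery.

    Per analyte: ROC AUC of observed dCt against the primary reference rule;
    the concordance-maximising cutoff and its error versus the configured
    assay cutoff; OPA at the configured cutoff; and agreement between the
    engine's POSITIVE/NEGATIVE calls and the latent assay truth
    (true dCt at-or-above cutoff) on validly called samples.
    """
    assay = assay or AssayConfig()
    cohort = generate(spec)
    calls = call_table(cohort.panels, assay)
    scored = score_table(cohort.ihc, cohort.fish, DEFAULT_RULES)
    truth = cohort.truth.set_index("sample_id")

    per: dict[str, AnalyteRecovery] = {}
    for analyte in ANALYTES:
        scores, labels = analyte_scores_and_labels(cohort, analyte, assay, calls, scored)
        if labels.sum() in (0, labels.size):
            per[analyte] = AnalyteRecovery(math.nan, math.nan, math.nan, math.nan, math.nan, 0)
            continue
        auc = roc(scores, labels).auc
        cutoff_est, _ = optimize_cutoff(scores, labels)
        cutoff = assay.cutoff(analyte)

        sub = calls[(calls["analyte"] == analyte)].set_index("sample_id")
        ref = scored[scored["rule_id"] == PRIMARY_RULES[analyte]].set_index("sample_id")["status"]
        table = build_table(sub["status"], ref)
        report = agreement_stats(table) if table.total else None

        decided = sub[sub["status"].isin(["POSITIVE", "NEGATIVE"])]
        true_dct = truth.loc[decided.index, f"dct_true_{analyte.lower()}"]
        true_call = np.where(true_dct >= cutoff, "POSITIVE", "NEGATIVE")
        agreement = float(np.mean(decided["status"].to_numpy() == true_call)) if len(decided) else math.nan

        per[analyte] = AnalyteRecovery(
            auc=auc,
            cutoff_estimate=cutoff_est,
            cutoff_error=cutoff_est - cutoff,
            opa=report.opa.estimate if report else math.nan,
            truth_agreement=agreement,
            n_used=int(scores.size),
        )
    return RecoveryReport(per_analyte=per)
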
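"""Synthetic survival cohorts with the dependency structure the iSEND
analyses assume, for testing every pipeline stage without patient data.

The generator samples covariates from configurable marginals, computes each
patient's iSEND group through the real scoring module (never by assigning a
latent label), and attaches group-specific exponential (or Weibull) event
times: the risk group causally determines the hazard, exactly the structure
the downstream survival analyses estimate. PFS is the minimum of an
independent progression process and death, so pfs_time <= os_time holds by
construction. Censoring emulates staggered accrual: entry uniform over an
accrual window with a single administrative cutoff, giving a reverse-KM
median follow-up near the configured target.

Haematology model: NLR1 is log-normal; delta-NLR is normal with a
mean-reversion correlation against the log-NLR1 driver (rho = -0.29,
calibrated once by Monte Carlo so the composite prevalence
P(NLR1 >= 5, dnlr >= 0) matches the 17.3% the generator targets while
keeping the configured medians and dispersions).

Also provides two deterministic fixtures: a 439-patient cohort reproducing
the published categorical count table cell-for-cell, and a 727-record
pre-exclusion cohort realising the study's exclusion cascade counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .cohort import PatientRecord
from .score import isend_score

LN2 = float(np.log(2.0))


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic PD-1/L1 monotherapy cohort.

    Defaults reproduce the pooled-cohort marginals and group-specific
    median survivals the analyses are designed around. Times in months.
    """

    n: int = 439
    seed: int = 0
    # covariate marginals
    p_male: float = 0.56
    p_ecog2plus: float = 0.187
    p_never_smoker: float = 0.173       # among patients with known history
    p_smoking_unknown: float = 0.025
    p_squamous: float = 0.269
    p_egfr_alk: float = 0.105
    p_egfr_alk_unknown: float = 0.032
    p_training: float = 0.362           # 159/439 split
    # haematology
    nlr1_median: float = 4.5
    nlr1_log_sigma: float = 0.55
    dnlr_median: float = 0.1
    dnlr_sd: float = 2.5
    nlr_mean_reversion_rho: float = -0.29   # calibrated: composite prevalence 17.3%
    # outcomes (months)
    group_os_medians: dict[str, float] = field(
        default_factory=lambda: {"good": 23.0, "intermediate": 13.4, "poor": 4.5})
    group_pfs_medians: dict[str, float] = field(
        default_factory=lambda: {"good": 6.5, "intermediate": 4.0, "poor": 1.9})
    chemo_pfs_median: float = 9.8
    chemo_os_median: float = 12.0
    event_time_family: str = "exponential"   # or "weibull"
    weibull_shape: float = 1.0
    # censoring: entry ~ U(0, accrual), administrative cutoff from study start;
    # defaults give potential follow-up ~ U(10, 26), reverse-KM median ~ 18
    accrual_months: float = 16.0
    admin_cutoff_months: float = 26.0
    # PD-L1
    pdl1_missing: float = 0.615
    pdl1_probs: dict[str, float] = field(
        default_factory=lambda: {"p0": 0.28, "p1_49": 0.44, "p50plus": 0.28})
    pdl1_group_association: float = 0.0   # 0 = independent of iSEND group

    def validate(self) -> None:
        probs = [self.p_male, self.p_ecog2plus, self.p_never_smoker,
                 self.p_smoking_unknown, self.p_squamous, self.p_egfr_alk,
                 self.p_egfr_alk_unknown, self.p_training, self.pdl1_missing,
                 *self.pdl1_probs.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.pdl1_probs.values()) - 1.0) > 1e-9:
            raise ValueError("pdl1 category probabilities must sum to 1")
        medians = [*self.group_os_medians.values(), *self.group_pfs_medians.values(),
                   self.chemo_pfs_median, self.chemo_os_median]
        if any(m <= 0 for m in medians):
            raise ValueError("all medians must be positive")
        for g in ("good", "intermediate", "poor"):
            if self.group_pfs_medians[g] >= self.group_os_medians[g]:
                raise ValueError("PFS median must be below OS median per group")
        if self.chemo_pfs_median >= self.chemo_os_median:
            raise ValueError("chemo PFS median must be below chemo OS median")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not -1.0 < self.nlr_mean_reversion_rho < 1.0:
            raise ValueError("mean-reversion rho must lie in (-1, 1)")
        if self.event_time_family not in ("exponential", "weibull"):
            raise ValueError("event_time_family must be 'exponential' or 'weibull'")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _sample_haematology(rng: np.random.Generator, cfg: SimConfig,
                        n: int) -> tuple[np.ndarray, np.ndarray]:
    """(nlr1, nlr2) with mean-reversion-correlated delta; nlr2 kept positive."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    nlr1 = np.exp(np.log(cfg.nlr1_median) + cfg.nlr1_log_sigma * z1)
    rho = cfg.nlr_mean_reversion_rho
    dnlr = cfg.dnlr_median + cfg.dnlr_sd * (rho * z1 + np.sqrt(1 - rho**2) * z2)
    # an NLR below 0.05 is not physiological; clipping (rather than
    # redrawing) keeps the invalid draws in the far-left dnlr tail, so the
    # dnlr median and the composite prevalence are unaffected
    nlr2 = np.maximum(nlr1 + dnlr, 0.05)
    return nlr1, nlr2


def generate_cohort(config: SimConfig) -> list[PatientRecord]:
    """Generate an analysis-ready PD-1/L1 monotherapy cohort.

    Deterministic given the seed; records pass cohort validation with zero
    diagnostics and need no exclusions.
    """
    return _generate(config, chemo=False)


def generate_chemo_cohort(config: SimConfig) -> list[PatientRecord]:
    """Generate a chemotherapy-only control cohort.

    Identical covariate model, but the event-time medians do not depend on
    the iSEND group — the generator encodes the negative-control claim that
    the score carries no information about chemotherapy outcome.
    """
    return _generate(config, chemo=True)


def _generate(cfg: SimConfig, chemo: bool) -> list[PatientRecord]:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    if n == 0:
        return []

    male = rng.random(n) < cfg.p_male
    ecog2plus = rng.random(n) < cfg.p_ecog2plus
    ecog = np.where(ecog2plus, rng.choice([2, 3], size=n, p=[0.8, 0.2]),
                    rng.integers(0, 2, size=n))
    smoke_u = rng.random(n)
    smoking = np.where(smoke_u < cfg.p_smoking_unknown, "unknown",
                       np.where(rng.random(n) < cfg.p_never_smoker, "never", "any"))
    squamous = rng.random(n) < cfg.p_squamous
    egfr_u = rng.random(n)
    egfr_alk = np.where(egfr_u < cfg.p_egfr_alk_unknown, "unknown",
                        np.where(rng.random(n) < cfg.p_egfr_alk, "yes", "no"))
    age = np.clip(np.round(rng.normal(66, 10, size=n)), 28, 91).astype(int)
    prior_lines = np.minimum(rng.geometric(0.6, size=n), 10)
    nlr1, nlr2 = _sample_haematology(rng, cfg, n)

    # risk group through the real scoring path
    groups = [
        isend_score("male" if male[i] else "female", int(ecog[i]),
                    float(nlr1[i]), float(nlr2[i] - nlr1[i])).group
        for i in range(n)
    ]

    # PD-L1: optional association shifts poor-group patients toward p0 and
    # good-group patients toward p50plus by the association weight
    pdl1 = np.full(n, "unknown", dtype=object)
    available = rng.random(n) >= cfg.pdl1_missing
    cats = list(cfg.pdl1_probs)
    base = np.array([cfg.pdl1_probs[c] for c in cats])
    for i in np.nonzero(available)[0]:
        probs = base.copy()
        a = cfg.pdl1_group_association
        if a > 0 and groups[i] in ("poor", "good"):
            target = "p0" if groups[i] == "poor" else "p50plus"
            j = cats.index(target)
            probs = (1 - a) * probs
            probs[j] += a
        pdl1[i] = rng.choice(cats, p=probs / probs.sum())

    os_med = np.array([
        cfg.chemo_os_median if chemo else cfg.group_os_medians[g] for g in groups])
    pfs_med = np.array([
        cfg.chemo_pfs_median if chemo else cfg.group_pfs_medians[g] for g in groups])
    if cfg.event_time_family == "exponential":
        # progression hazard chosen so min(progression, death) has the
        # configured PFS median exactly: lam_prog = ln2/m_pfs - ln2/m_os
        lam_os = LN2 / os_med
        lam_prog = LN2 / pfs_med - lam_os
        os_raw = rng.exponential(1.0, size=n) / lam_os
        prog_raw = rng.exponential(1.0, size=n) / lam_prog
    else:
        k = cfg.weibull_shape
        os_raw = (os_med / LN2 ** (1.0 / k)) * rng.weibull(k, size=n)
        prog_raw = (pfs_med / LN2 ** (1.0 / k)) * rng.weibull(k, size=n)
    pfs_raw = np.minimum(prog_raw, os_raw)

    entry = rng.uniform(0.0, cfg.accrual_months, size=n)
    censor = cfg.admin_cutoff_months - entry
    os_time = np.minimum(os_raw, censor)
    os_event = (os_raw <= censor).astype(int)
    pfs_time = np.minimum(pfs_raw, censor)
    pfs_event = (pfs_raw <= censor).astype(int)

    training = rng.random(n) < cfg.p_training
    records = []
    for i in range(n):
        records.append(PatientRecord(
            patient_id=f"{'C' if chemo else 'S'}{cfg.seed}-{i:05d}",
            sex="male" if male[i] else "female",
            age=int(age[i]),
            smoking=str(smoking[i]),
            ecog=int(ecog[i]),
            histology="squamous" if squamous[i] else "non_squamous",
            egfr_alk=str(egfr_alk[i]),
            nlr1=float(nlr1[i]),
            nlr2=float(nlr2[i]),
            pdl1=str(pdl1[i]),
            prior_lines=int(prior_lines[i]),
            treatment="chemo_only" if chemo else "pd1_mono",
            line_setting="post_platinum",
            cohort="chemo" if chemo else ("training" if training[i] else "validation"),
            os_time=float(os_time[i]),
            os_event=int(os_event[i]),
            pfs_time=float(pfs_time[i]),
            pfs_event=int(pfs_event[i]),
        ))
    return records


# ---------------------------------------------------------------------------
# deterministic fixtures

#: categorical count cells per cohort: variable -> level -> (training, validation)
_TABLE1_COUNTS = {
    "sex": {"male": (85, 161), "female": (74, 119)},
    "smoking": {"unknown": (2, 9), "any": (132, 220), "never": (25, 51)},
    "ecog": {"ecog_0_1": (125, 232), "ecog_2_3": (34, 48)},
    "histology": {"squamous": (40, 78), "non_squamous": (119, 202)},
    "egfr_alk": {"unknown": (0, 14), "no": (142, 237), "yes": (17, 29)},
    "composite": {"others": (135, 228), "composite": (24, 52)},
}
_COHORT_SIZES = {"training": 159, "validation": 280}


def _fill_column(level_counts: dict[str, tuple[int, int]], col: int) -> list[str]:
    out: list[str] = []
    for level, counts in level_counts.items():
        out.extend([level] * counts[col])
    return out


def make_table1_fixture() -> list[PatientRecord]:
    """A deterministic 439-patient cohort matching the published categorical
    count table cell-for-cell (synthetic: columns are filled independently,
    so the joint distribution is arbitrary; continuous variables carry
    arbitrary valid values).
    """
    records: list[PatientRecord] = []
    for col, (cohort, size) in enumerate(_COHORT_SIZES.items()):
        columns = {var: _fill_column(levels, col)
                   for var, levels in _TABLE1_COUNTS.items()}
        assert all(len(v) == size for v in columns.values())
        for i in range(size):
            composite = columns["composite"][i] == "composite"
            nlr1, nlr2 = (6.0, 6.5) if composite else (3.0, 2.9)
            records.append(PatientRecord(
                patient_id=f"T1-{cohort}-{i:04d}",
                sex=columns["sex"][i],
                age=66,
                smoking=columns["smoking"][i],
                ecog=0 if columns["ecog"][i] == "ecog_0_1" else 2,
                histology=columns["histology"][i],
                egfr_alk=columns["egfr_alk"][i],
                nlr1=nlr1,
                nlr2=nlr2,
                pdl1="unknown",
                prior_lines=1,
                treatment="pd1_mono",
                line_setting="post_platinum",
                cohort=cohort,
                os_time=12.0,
                os_event=i % 2,
                pfs_time=6.0,
                pfs_event=1,
            ))
    return records


def make_exclusion_cascade_fixture(seed: int = 0) -> list[PatientRecord]:
    """A synthetic 727-record pre-exclusion cohort realising the study's
    exclusion counts: 36 first-line, 44 combination treatment, 31 duplicate
    ids, 177 missing NLR — leaving a 439-patient analysis set.
    """
    cfg = SimConfig(n=439, seed=seed)
    clean = generate_cohort(cfg)
    extra_cfg = dataclasses.replace(cfg, n=36 + 44 + 177, seed=seed + 1)
    extras = generate_cohort(extra_cfg)
    for i, r in enumerate(extras):
        r.patient_id = f"X{seed}-{i:05d}"
        if i < 36:
            r.line_setting = "first_line"
        elif i < 80:
            r.line_setting = "combination"
        elif i % 3 == 0:
            r.nlr1 = None
        else:
            r.nlr2 = None
    duplicates = []
    for i in range(31):
        dup = dataclasses.replace(clean[i])
        dup.age = min(dup.age + 1, 91)  # duplicate id; the later entry is dropped
        duplicates.append(dup)
    # clean records first so keep-first retains the originals; the excluded
    # material is shuffled after them
    rng = np.random.default_rng(seed + 2)
    tail = extras + duplicates
    order = rng.permutation(len(tail))
    return clean + [tail[k] for k in order]
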
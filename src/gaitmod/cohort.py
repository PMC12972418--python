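"""Synthetic geriatric mobility cohort generator.

Emulates the statistical structure a statin/gait moderation analysis
assumes: a cohort of adults aged 60-100 with Table-1-style covariate
prevalences, drug exposures confounded by comorbidity (statin assignment
follows a logistic model on conditions, concomitant drugs and
demographics), gait outcomes generated from a linear model with a
treatment x moderator interaction on gait speed reserve (GSR), free-text
renderings of medications and conditions with typos, brand names and
negations, and optional missingness.

The defaults describe the analyzed cohort of the motivating study:
n = 5519, mean age 76.4 (SD 7.4), 54% female, statin prevalence 31%,
aspirin 28%, mean usual gait speed 105 cm/s and mean GSR 41.3 cm/s,
with aspirin as the default moderator (interaction 5.76 cm/s,
treatment effect -3.43 cm/s in the aspirin-free stratum).

Marginal prevalence targets are enforced by calibrating each logistic
intercept against the realized linear score (bisection), so confounding
strength and marginal rates can be set independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from ._lexicon_data import CONDITIONS, DRUG_CLASSES
from .annotation import Lexicon, default_condition_lexicon, default_drug_lexicon

__all__ = [
    "CohortSpec",
    "TextNoise",
    "generate_cohort",
    "render_text",
    "render_cohort_text",
    "inject_missingness",
    "DEMOGRAPHICS",
]

DEMOGRAPHICS = ["age", "female", "bmi", "physically_active", "walking_aid", "fall_history"]

# Overall prevalences as printed in the study's baseline table.
CONDITION_PREVALENCE = {
    "vascular_disease": 0.17,
    "chronic_kidney_disease": 0.088,
    "congestive_heart_failure": 0.18,
    "coronary_heart_disease": 0.13,
    "depression": 0.21,
    "diabetes": 0.13,
    "osteoarthritis": 0.24,
    "hyperlipidemia": 0.23,
    "hypertension": 0.48,
    "low_back_pain": 0.22,
    "parkinson": 0.024,
    "pulmonary_disease": 0.25,
}

DRUG_PREVALENCE = {
    "statin": 0.31,
    "five_alpha_reductase_inhibitor": 0.024,
    "acei": 0.17,
    "potassium_sparing_diuretic": 0.020,
    "alpha_adrenergic_antagonist": 0.067,
    "antipsychotic": 0.061,
    "aspirin": 0.28,
    "benzodiazepine": 0.16,
    "beta_blocker": 0.25,
    "biguanide": 0.090,
    "dihydropyridine": 0.17,
    "insulin": 0.016,
    "opioid": 0.033,
    "ppi": 0.20,
    "sartan": 0.24,
    "ssri": 0.10,
    "loop_diuretic": 0.085,
    "thiazide": 0.14,
    "sulphonylurea": 0.032,
    "tricyclic_antidepressant": 0.031,
    "thyroid_hormone": 0.055,
    "uric_acid_inhibitor": 0.034,
}

# burden = shared latent comorbidity factor; age in SD units
_CONDITION_LOADINGS = {
    # condition: (age coefficient, burden coefficient)
    "vascular_disease": (0.45, 0.9),
    "chronic_kidney_disease": (0.5, 0.8),
    "congestive_heart_failure": (0.5, 0.9),
    "coronary_heart_disease": (0.35, 1.0),
    "depression": (-0.1, 0.3),
    "diabetes": (0.1, 0.7),
    "osteoarthritis": (0.15, 0.3),
    "hyperlipidemia": (0.0, 0.8),
    "hypertension": (0.3, 0.8),
    "low_back_pain": (0.0, 0.2),
    "parkinson": (0.2, 0.2),
    "pulmonary_disease": (0.1, 0.4),
}

# drug: {condition-or-demographic: log-odds}
_DRUG_LINKS = {
    "acei": {"hypertension": 1.2, "congestive_heart_failure": 0.6, "diabetes": 0.4},
    "sartan": {"hypertension": 1.2},
    "beta_blocker": {
        "hypertension": 0.8,
        "coronary_heart_disease": 1.0,
        "congestive_heart_failure": 0.8,
    },
    "dihydropyridine": {"hypertension": 1.2},
    "thiazide": {"hypertension": 1.0},
    "loop_diuretic": {"congestive_heart_failure": 1.5, "chronic_kidney_disease": 0.8},
    "potassium_sparing_diuretic": {"congestive_heart_failure": 1.2},
    "aspirin": {
        "coronary_heart_disease": 1.8,
        "vascular_disease": 1.2,
        "diabetes": 0.3,
    },
    "biguanide": {"diabetes": 3.5},
    "sulphonylurea": {"diabetes": 3.0},
    "insulin": {"diabetes": 3.0},
    "ssri": {"depression": 1.5},
    "tricyclic_antidepressant": {"depression": 0.8, "low_back_pain": 0.5},
    "opioid": {"low_back_pain": 1.0, "osteoarthritis": 0.8},
    "ppi": {"coronary_heart_disease": 0.4},
    "antipsychotic": {"depression": 0.5},
    "alpha_adrenergic_antagonist": {"hypertension": 0.3, "female": -2.0},
    "five_alpha_reductase_inhibitor": {"female": None},  # male-only (overlap example)
    "thyroid_hormone": {"female": 0.8},
    "uric_acid_inhibitor": {"chronic_kidney_disease": 0.5, "hypertension": 0.3},
    "benzodiazepine": {"depression": 0.6},
}

# statin assignment: log-odds on conditions, concomitant drugs, demographics
_STATIN_COEFS = {
    "hyperlipidemia": 2.1,
    "coronary_heart_disease": 1.4,
    "vascular_disease": 0.8,
    "diabetes": 0.5,
    "aspirin": 1.3,
    "beta_blocker": 0.7,
    "acei": 0.5,
    "dihydropyridine": 0.55,
    "biguanide": 0.5,
    "female": -0.5,
    "age_sd": 0.08,
    "bmi_sd": 0.2,
}

# linear effects on usual gait speed (cm/s), covariates centered
_USUAL_EFFECTS = {
    "age_sd": -6.5,
    "female": -2.0,
    "bmi_sd": -1.0,
    "physically_active": 4.0,
    "walking_aid": -12.0,
    "fall_history": -3.0,
    "parkinson": -10.0,
    "osteoarthritis": -3.0,
    "congestive_heart_failure": -4.0,
    "pulmonary_disease": -2.0,
    "vascular_disease": -3.0,
}

# linear effects on gait speed reserve (cm/s), covariates centered
_GSR_EFFECTS = {
    "age_sd": -3.0,
    "female": -1.0,
    "bmi_sd": -0.7,
    "physically_active": 3.0,
    "walking_aid": -6.0,
    "fall_history": -2.0,
    "parkinson": -5.0,
    "osteoarthritis": -2.0,
    "congestive_heart_failure": -2.0,
    "pulmonary_disease": -1.5,
    "vascular_disease": -2.0,
    "chronic_kidney_disease": -1.5,
    "depression": -1.0,
}


@dataclass
class TextNoise:
    """Noise model for the free-text renderings."""

    typo_rate: float = 0.05
    brand_rate: float = 0.30
    negation_rate: float = 0.05
    german_rate: float = 0.30
    dose_rate: float = 0.30
    filler_rate: float = 0.30  # "known ...", "... seit 2012" around conditions
    typo_min_len: int = 8  # one edit on a token this long keeps similarity >= 0.875

    @classmethod
    def none(cls) -> "TextNoise":
        return cls(typo_rate=0.0, brand_rate=0.0, negation_rate=0.0, german_rate=0.0,
                   dose_rate=0.0, filler_rate=0.0)


@dataclass
class CohortSpec:
    """Generating conditions of a synthetic cohort."""

    n: int = 5519
    seed: int = 0
    age_mean: float = 76.43
    age_sd: float = 7.36
    age_range: tuple[float, float] = (60.0, 100.0)
    female: float = 0.54
    bmi_mean: float = 25.73
    bmi_sd: float = 4.41
    physically_active: float = 0.87
    walking_aid: float = 0.14
    fall_history: float = 0.30
    condition_prevalence: dict = field(default_factory=lambda: dict(CONDITION_PREVALENCE))
    drug_prevalence: dict = field(default_factory=lambda: dict(DRUG_PREVALENCE))
    confounding: float = 1.0  # scales every treatment-assignment coefficient
    moderator: str = "aspirin"
    treatment_effect: float = -3.43  # b1: statin effect on GSR at moderator = 0
    moderator_effect: float = 1.0  # b2
    interaction: float = 5.76  # b3
    usual_statin_effect: float = -0.9
    gsr_mean: float = 41.3
    usual_mean: float = 105.0
    gsr_sd: float = 12.0
    usual_sd: float = 14.0
    text_noise: TextNoise = field(default_factory=TextNoise)
    heavy_tails: bool = False  # Student-t(5) residuals for robustness checks

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.gsr_sd <= 0 or self.usual_sd <= 0:
            raise ValueError("residual sd must be positive")
        for name, p in {**self.condition_prevalence, **self.drug_prevalence}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name} outside [0, 1]")
        if self.moderator not in self.drug_prevalence:
            raise ValueError(f"unknown moderator {self.moderator!r}")

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


def _calibrated_bernoulli(rng: np.random.Generator, target: float, score: np.ndarray) -> np.ndarray:
    """Draw Bernoulli(sigmoid(c + score)) with c solved so the expected
    prevalence over the sample equals the target."""
    if target <= 0.0:
        return np.zeros(score.shape[0], dtype=float)
    if target >= 1.0:
        return np.ones(score.shape[0], dtype=float)

    def gap(c: float) -> float:
        return float(np.mean(expit(c + score)) - target)

    c = brentq(gap, -30.0, 30.0)
    return (rng.random(score.shape[0]) < expit(c + score)).astype(float)


def _residual(rng: np.random.Generator, n: int, sd: float, heavy: bool) -> np.ndarray:
    if heavy:
        return rng.standard_t(5, n) * sd / np.sqrt(5.0 / 3.0)
    return rng.normal(0.0, sd, n)


def generate_cohort(
    spec: CohortSpec,
    seed: Optional[int] = None,
    text: bool = True,
    drug_lexicon: Optional[Lexicon] = None,
    condition_lexicon: Optional[Lexicon] = None,
) -> pd.DataFrame:
    """Generate a cohort as one row per patient.

    Columns: patient_id, demographics (age, female, sex, bmi,
    physically_active, walking_aid, fall_history), 12 condition flags,
    22 drug flags, ascvd and normal_cognition stratum flags, gait
    outcomes (usual_speed, max_speed, gsr) and, when ``text=True``,
    med_text / comorbid_text renderings.  Deterministic given spec and
    seed; negative GSR draws are resampled (truncation at zero).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n

    lo, hi = spec.age_range
    a, b = (lo - spec.age_mean) / spec.age_sd, (hi - spec.age_mean) / spec.age_sd
    age = truncnorm.rvs(a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng)
    age_sd_units = (age - spec.age_mean) / spec.age_sd
    female = (rng.random(n) < spec.female).astype(float)
    bmi = rng.normal(spec.bmi_mean, spec.bmi_sd, n)
    bmi_sd_units = (bmi - spec.bmi_mean) / spec.bmi_sd
    active = (rng.random(n) < spec.physically_active).astype(float)
    walking_aid = (rng.random(n) < expit(
        np.log(spec.walking_aid / (1 - spec.walking_aid)) + 0.8 * age_sd_units
    )).astype(float)
    fall = (rng.random(n) < expit(
        np.log(spec.fall_history / (1 - spec.fall_history)) + 0.4 * age_sd_units
    )).astype(float)

    burden = rng.normal(0.0, 1.0, n)
    conditions: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        p = spec.condition_prevalence.get(cond, 0.0)
        age_c, burden_c = _CONDITION_LOADINGS.get(cond, (0.0, 0.5))
        score = age_c * age_sd_units + burden_c * burden
        conditions[cond] = _calibrated_bernoulli(rng, p, score)

    demo = {"female": female, "age_sd": age_sd_units, "bmi_sd": bmi_sd_units}
    drugs: dict[str, np.ndarray] = {}
    for drug in DRUG_CLASSES:
        if drug == "statin":
            continue
        p = spec.drug_prevalence.get(drug, 0.0)
        links = _DRUG_LINKS.get(drug, {})
        if links.get("female", 0.0) is None:  # sex-restricted (male-only) drug
            score = np.zeros(n)
            male = female == 0
            p_male = min(1.0, p / max(float(male.mean()), 1e-9))
            flags = np.zeros(n)
            if male.any():
                flags[male] = _calibrated_bernoulli(rng, p_male, score[male])
            drugs[drug] = flags
            continue
        score = np.zeros(n)
        for key, coef in links.items():
            src = conditions.get(key)
            if src is None:
                src = demo[key]
                center = spec.female if key == "female" else 0.0
            else:
                center = spec.condition_prevalence.get(key, 0.0)
            score = score + coef * (src - center)
        drugs[drug] = _calibrated_bernoulli(rng, p, score)

    score = np.zeros(n)
    for key, coef in _STATIN_COEFS.items():
        coef = coef * spec.confounding
        if key in conditions:
            score += coef * (conditions[key] - spec.condition_prevalence.get(key, 0.0))
        elif key in drugs:
            score += coef * (drugs[key] - spec.drug_prevalence.get(key, 0.0))
        elif key == "female":
            score += coef * (female - spec.female)
        else:
            score += coef * demo[key]
    statin = _calibrated_bernoulli(rng, spec.drug_prevalence["statin"], score)
    drugs["statin"] = statin

    covar = {
        "female": (female, spec.female),
        "age_sd": (age_sd_units, 0.0),
        "bmi_sd": (bmi_sd_units, 0.0),
        "physically_active": (active, spec.physically_active),
        "walking_aid": (walking_aid, spec.walking_aid),
        "fall_history": (fall, spec.fall_history),
    }

    def linear(effects: dict) -> np.ndarray:
        lp = np.zeros(n)
        for key, coef in effects.items():
            if key in conditions:
                lp += coef * (conditions[key] - spec.condition_prevalence.get(key, 0.0))
            else:
                x, center = covar[key]
                lp += coef * (x - center)
        return lp

    m = drugs[spec.moderator]
    p_m = spec.drug_prevalence[spec.moderator]
    xm = statin * m
    usual = (
        spec.usual_mean
        + linear(_USUAL_EFFECTS)
        + spec.usual_statin_effect * (statin - spec.drug_prevalence["statin"])
        + _residual(rng, n, spec.usual_sd, spec.heavy_tails)
    )
    usual = np.clip(usual, 20.0, None)

    gsr_lp = (
        spec.gsr_mean
        + linear(_GSR_EFFECTS)
        + spec.treatment_effect * (statin - spec.drug_prevalence["statin"])
        + spec.moderator_effect * (m - p_m)
        + spec.interaction * (xm - float(xm.mean()))
    )
    gsr = gsr_lp + _residual(rng, n, spec.gsr_sd, spec.heavy_tails)
    for _ in range(50):  # truncate below zero by resampling the residual
        neg = gsr < 0
        if not neg.any():
            break
        gsr[neg] = gsr_lp[neg] + _residual(rng, int(neg.sum()), spec.gsr_sd, spec.heavy_tails)
    np.clip(gsr, 0.1, None, out=gsr)

    frame = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "age": age,
            "female": female,
            "sex": np.where(female == 1, "F", "M"),
            "bmi": bmi,
            "physically_active": active,
            "walking_aid": walking_aid,
            "fall_history": fall,
        }
    )
    for cond in CONDITIONS:
        frame[cond] = conditions[cond]
    for drug in DRUG_CLASSES:
        frame[drug] = drugs[drug]
    frame["ascvd"] = (
        (conditions["coronary_heart_disease"] + conditions["vascular_disease"]) > 0
    ).astype(float)
    frame["normal_cognition"] = (
        rng.random(n) < expit(np.log(0.55 / 0.45) - 0.5 * age_sd_units)
    ).astype(float)
    frame["usual_speed"] = usual
    frame["gsr"] = gsr
    frame["max_speed"] = usual + gsr

    if text:
        drug_lexicon = drug_lexicon or default_drug_lexicon()
        condition_lexicon = condition_lexicon or default_condition_lexicon()
        render_cohort_text(frame, drug_lexicon, condition_lexicon, spec.text_noise, rng)
    return frame


# ---------------------------------------------------------------------------
# free-text rendering

_NEGATION_TEMPLATES_EN = ["does not take {t}", "stopped {t}", "no {t}"]
_NEGATION_TEMPLATES_DE = ["kein {t}", "nimmt nicht {t}"]
_DOSES = ["10mg", "20mg", "40mg", "50mg", "100mg", "500mg"]
_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _typo(term: str, rng: np.random.Generator) -> str:
    """One random character edit (substitution, deletion, insertion or
    adjacent transposition)."""
    kind = rng.integers(0, 4)
    i = int(rng.integers(0, len(term)))
    if kind == 0:  # substitution
        c = _LETTERS[rng.integers(0, 26)]
        while c == term[i]:
            c = _LETTERS[rng.integers(0, 26)]
        return term[:i] + c + term[i + 1 :]
    if kind == 1:  # deletion
        return term[:i] + term[i + 1 :]
    if kind == 2:  # insertion
        c = _LETTERS[rng.integers(0, 26)]
        return term[:i] + c + term[i:]
    if len(term) < 2:
        return term + _LETTERS[rng.integers(0, 26)]
    i = min(i, len(term) - 2)
    if term[i] == term[i + 1]:  # transposing equal chars is a no-op; substitute
        c = _LETTERS[rng.integers(0, 26)]
        while c == term[i]:
            c = _LETTERS[rng.integers(0, 26)]
        return term[:i] + c + term[i + 1 :]
    return term[:i] + term[i + 1] + term[i] + term[i + 2 :]


def _terms_by_code(lexicon: Lexicon) -> dict[str, dict[str, list[str]]]:
    out: dict[str, dict[str, list[str]]] = {}
    for e in lexicon.entries:
        out.setdefault(e.code, {}).setdefault(e.kind, []).append(e.term)
        out[e.code].setdefault(e.language, []).append(e.term)
    return out


def _pick(rng: np.random.Generator, items: list[str]) -> str:
    return items[int(rng.integers(0, len(items)))]


def render_text(
    drug_flags: dict[str, bool],
    condition_flags: dict[str, bool],
    drug_lexicon: Lexicon,
    condition_lexicon: Lexicon,
    noise: TextNoise,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Render one patient's flags into medication and comorbidity text."""
    drug_terms = _terms_by_code(drug_lexicon)
    cond_terms = _terms_by_code(condition_lexicon)

    med_items: list[str] = []
    negated_items: list[str] = []
    for code, held in drug_flags.items():
        if code not in drug_terms:
            raise ValueError(f"no lexicon coverage for drug class {code!r}")
        pools = drug_terms[code]
        if held:
            pool = pools.get("drug-brand") if (
                rng.random() < noise.brand_rate and "drug-brand" in pools
            ) else pools.get("drug-generic", pools.get("drug-brand"))
            term = _pick(rng, pool)
            if noise.typo_rate and len(term) >= noise.typo_min_len and rng.random() < noise.typo_rate:
                term = _typo(term, rng)
            if rng.random() < noise.dose_rate:
                term = f"{term} {_pick(rng, _DOSES)}"
            med_items.append(term)
        elif noise.negation_rate and rng.random() < noise.negation_rate:
            term = _pick(rng, pools.get("drug-generic", pools.get("drug-brand")))
            templates = _NEGATION_TEMPLATES_EN + _NEGATION_TEMPLATES_DE
            negated_items.append(_pick(rng, templates).format(t=term))
    # negated mentions trail the actives so a cue's look-behind scope
    # cannot swallow a genuinely held medication
    med_items = med_items + negated_items

    cond_items: list[str] = []
    for code, held in condition_flags.items():
        if not held:
            continue
        if code not in cond_terms:
            raise ValueError(f"no lexicon coverage for condition {code!r}")
        pools = cond_terms[code]
        lang = "de" if (rng.random() < noise.german_rate and "de" in pools) else "en"
        term = _pick(rng, pools.get(lang) or pools["en"])
        if noise.typo_rate and rng.random() < noise.typo_rate:
            words = term.split()
            j = int(rng.integers(0, len(words)))
            if len(words[j]) >= noise.typo_min_len:
                words[j] = _typo(words[j], rng)
            term = " ".join(words)
        if rng.random() < noise.filler_rate:
            term = f"known {term}" if lang == "en" else f"{term} seit {rng.integers(1990, 2023)}"
        cond_items.append(term)

    if not med_items:  # drug-free is a known state, distinct from missing history
        med_items = ["no regular medication"]
    return ", ".join(med_items), ", ".join(cond_items)


def render_cohort_text(
    frame: pd.DataFrame,
    drug_lexicon: Lexicon,
    condition_lexicon: Lexicon,
    noise: TextNoise,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Add med_text / comorbid_text columns in place (and return the frame)."""
    med_texts, cond_texts = [], []
    for _, row in frame.iterrows():
        med, cond = render_text(
            {d: bool(row[d]) for d in DRUG_CLASSES},
            {c: bool(row[c]) for c in CONDITIONS},
            drug_lexicon,
            condition_lexicon,
            noise,
            rng,
        )
        med_texts.append(med)
        cond_texts.append(cond)
    frame["med_text"] = med_texts
    frame["comorbid_text"] = cond_texts
    return frame


def inject_missingness(
    frame: pd.DataFrame,
    rates: dict[str, float],
    rng: np.random.Generator,
    mar_by: Optional[str] = None,
    mar_ratio: float = 1.0,
) -> pd.DataFrame:
    """Set fields missing at the given per-field rates (MCAR by default).

    The pseudo-field "gait" blanks usual_speed and max_speed jointly.
    With ``mar_by`` set to a binary column, rows at level 1 have their
    missingness rate multiplied by ``mar_ratio`` (missing at random by
    treatment), which exercises the missingness-balancing property of
    the propensity weights.
    """
    out = frame.copy()
    n = len(out)
    for field_name, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {field_name} outside [0, 1]")
        if rate == 0.0:
            continue
        p = np.full(n, rate)
        if mar_by is not None:
            p = np.where(np.asarray(out[mar_by], dtype=float) == 1.0,
                         np.minimum(rate * mar_ratio, 1.0), rate)
        mask = rng.random(n) < p
        if field_name == "gait":
            out.loc[mask, ["usual_speed", "max_speed", "gsr"]] = np.nan
        elif field_name in ("med_text", "comorbid_text"):
            out.loc[mask, field_name] = None
        else:
            out.loc[mask, field_name] = np.nan
    return out
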
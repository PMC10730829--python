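"""Synthetic medical-helpline cohorts with planted stroke structure.

Real emergency-call data are locked behind patient-privacy law, so the whole
pipeline is exercised on generated cohorts that reproduce the statistical
structure the analysis assumes: a rare-event helpline (ground-truth stroke
prevalence 0.25% by default), an emergency line with ~10x the prevalence used
only as supplementary training data, patient demographics that differ sharply
by stroke status, a stroke registry with noisy patient-reported onset times
(including onsets outside the -72h/+24h linkage window and subarachnoid
haemorrhage entries, both of which the ground-truth labelling must exclude),
call-taker triage with configurable sensitivity and PPV, calls with a missing
diagnostic category, and transcripts in which stroke calls over-express a
small set of indicator words against a Zipf-distributed background lexicon.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfigurationError",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "simulate_calltaker",
    "implied_calltaker_fpr",
    "DEFAULT_INDICATOR_WORDS",
    "DEFAULT_DISTRACTOR_WORDS",
]

#: Stroke-marker tokens planted in stroke-call transcripts.  Loosely modelled
#: on the vocabulary that dominates positive occlusion rankings in triage
#: transcripts (dispatch terms, laterality, classic deficit descriptions).
DEFAULT_INDICATOR_WORDS = (
    "ambulance",
    "blood_clot",
    "left",
    "right",
    "double_vision",
    "suddenly",
    "arm",
    "stroke",
    "numb",
    "slurred",
)

#: Non-stroke markers planted in non-stroke transcripts (unrelated complaints,
#: routine-care vocabulary).
DEFAULT_DISTRACTOR_WORDS = (
    "tetanus",
    "pregnant",
    "bandage",
    "fever",
    "swollen",
    "prescription",
    "pneumonia",
    "stool",
    "bleeding",
    "knee",
)

_NON_STROKE_CATEGORIES = ("infection", "injury", "abdominal_pain", "respiratory", "other")
_STROKE_TYPES = ("ischaemic", "tia", "haemorrhagic")
_STROKE_TYPE_P = (0.7, 0.2, 0.1)


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent generator configurations."""


def implied_calltaker_fpr(prevalence: float, sensitivity: float, ppv: float) -> float:
    """Call-taker false-positive rate implied by (prevalence, sensitivity, PPV).

    Triage performance is reported as sensitivity and PPV; with prevalence p
    these jointly determine the false-positive rate on non-stroke calls::

        FPR = p * sens * (1 - PPV) / ((1 - p) * PPV)

    which must lie in [0, 1] for the triple to be feasible.
    """
    if ppv <= 0 or prevalence >= 1:
        raise ConfigurationError("PPV must be > 0 and prevalence < 1")
    return prevalence * sensitivity * (1.0 - ppv) / ((1.0 - prevalence) * ppv)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    The defaults emulate the reference Copenhagen cohort: rare stroke on the
    helpline, a higher-prevalence emergency line used only for training, older
    and more often male stroke patients, call-taker sensitivity 52.7% at PPV
    17.1%, 40% of calls without a diagnostic category, and a test year that
    carries ~27% of helpline volume.
    """

    n_calls: int = 50_000
    #: Rate of ground-truth-positive helpline calls (non-SAH, onset inside the
    #: linkage window).  Registry entries for SAH and out-of-window cases are
    #: generated on top of this rate.
    stroke_prevalence: float = 0.0025
    line_mix: float = 0.10  # fraction of calls on the emergency line
    emergency_prevalence: float = 0.025
    age_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"stroke": (71.0, 13.4), "non_stroke": (44.0, 20.0)}
    )
    age_bounds: tuple[float, float] = (18.0, 105.0)
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"stroke": 0.461, "non_stroke": 0.555}
    )
    calltaker_sensitivity: float = 0.527
    calltaker_ppv: float = 0.171
    #: Onset - call_start offset (hours) for in-window registry entries.
    onset_window_h: tuple[float, float] = (-48.0, 12.0)
    #: Fraction of registry entries whose onset falls outside [-72h, +24h].
    outside_window_fraction: float = 0.05
    sah_fraction: float = 0.05
    missing_category_fraction: float = 0.40
    vocab_size: int = 2_000
    zipf_exponent: float = 1.1
    indicator_words: Sequence[str] = DEFAULT_INDICATOR_WORDS
    indicator_rate: float = 0.40  # per indicator word, per stroke call
    indicator_background_rate: float = 0.005  # leakage into non-stroke calls
    distractor_words: Sequence[str] = DEFAULT_DISTRACTOR_WORDS
    distractor_rate: float = 0.40
    distractor_background_rate: float = 0.05
    doc_length_mean: float = 40.0
    doc_length_min: int = 5
    #: Token-substitution rate emulating transcription noise: each token is
    #: replaced by a random lexicon token with this probability.
    token_substitution_rate: float = 0.0
    years: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019, 2020, 2021)
    test_year: int = 2021
    test_year_share: float = 0.27  # share of calls falling in the test year
    seed: int = 0

    @property
    def implied_fpr(self) -> float:
        return implied_calltaker_fpr(
            self.stroke_prevalence, self.calltaker_sensitivity, self.calltaker_ppv
        )

    def validate(self) -> None:
        fractions = {
            "stroke_prevalence": self.stroke_prevalence,
            "line_mix": self.line_mix,
            "emergency_prevalence": self.emergency_prevalence,
            "calltaker_sensitivity": self.calltaker_sensitivity,
            "calltaker_ppv": self.calltaker_ppv,
            "outside_window_fraction": self.outside_window_fraction,
            "sah_fraction": self.sah_fraction,
            "missing_category_fraction": self.missing_category_fraction,
            "indicator_rate": self.indicator_rate,
            "indicator_background_rate": self.indicator_background_rate,
            "distractor_rate": self.distractor_rate,
            "distractor_background_rate": self.distractor_background_rate,
            "token_substitution_rate": self.token_substitution_rate,
            "test_year_share": self.test_year_share,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        if not 0.0 < self.stroke_prevalence < 1.0:
            raise ConfigurationError("stroke_prevalence must lie in (0, 1)")
        if self.n_calls <= 0:
            raise ConfigurationError("n_calls must be positive")
        fpr = self.implied_fpr
        if not 0.0 <= fpr <= 1.0:
            raise ConfigurationError(
                "infeasible (prevalence, sensitivity, PPV) triple: implied "
                f"call-taker FPR = {fpr:.6g} outside [0, 1]"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_params"] = {k: list(v) for k, v in self.age_params.items()}
        d["female_fraction"] = dict(self.female_fraction)
        for key in ("indicator_words", "distractor_words", "years"):
            d[key] = list(d[key])
        d["age_bounds"] = list(self.age_bounds)
        d["onset_window_h"] = list(self.onset_window_h)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "age_params" in d:
            d["age_params"] = {k: tuple(v) for k, v in d["age_params"].items()}
        for key in ("indicator_words", "distractor_words", "years", "age_bounds", "onset_window_h"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """One generated cohort: call records, registry, transcripts and truth."""

    calls: pd.DataFrame
    registry: pd.DataFrame
    transcripts: dict[str, list[str]]
    truth: pd.Series  # call_id -> planted ground-truth stroke status
    config: GeneratorConfig

    def to_files(self, directory: str | Path) -> None:
        """Write calls.csv, registry.csv and transcripts.jsonl."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.calls.to_csv(directory / "calls.csv", index=False)
        self.registry.to_csv(directory / "registry.csv", index=False)
        with open(directory / "transcripts.jsonl", "w") as fh:
            for call_id, tokens in self.transcripts.items():
                fh.write(json.dumps({"call_id": call_id, "tokens": tokens}) + "\n")

    @staticmethod
    def read_calls(path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path, parse_dates=["call_start"], keep_default_na=False, na_values=[""])

    @staticmethod
    def read_registry(path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path, parse_dates=["onset_time"])

    @staticmethod
    def read_transcripts(path: str | Path) -> dict[str, list[str]]:
        transcripts = {}
        with open(path) as fh:
            for line in fh:
                obj = json.loads(line)
                transcripts[obj["call_id"]] = obj["tokens"]
        return transcripts


def simulate_calltaker(
    truth: Sequence[bool] | np.ndarray, sens: float, fpr: float, seed: int
) -> np.ndarray:
    """Simulate call-taker triage labels for a sequence of true statuses.

    Each call is labelled positive independently: with probability ``sens``
    for true stroke calls and ``fpr`` for non-stroke calls.
    """
    if not 0.0 <= sens <= 1.0:
        raise ConfigurationError(f"sensitivity {sens} outside [0, 1]")
    if not 0.0 <= fpr <= 1.0:
        raise ConfigurationError(f"fpr {fpr} outside [0, 1]")
    truth = np.asarray(truth, dtype=bool)
    rng = np.random.default_rng(seed)
    u = rng.random(truth.shape[0])
    return np.where(truth, u < sens, u < fpr)


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))


def _truncnorm_ages(mean: float, sd: float, bounds: tuple[float, float], size: int, rng) -> np.ndarray:
    lo, hi = bounds
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full cohort under ``config``; deterministic in the seed."""
    config.validate()
    n = config.n_calls
    seed = config.seed

    # --- line and calendar placement -------------------------------------
    rng = np.random.default_rng(_stage_seed(seed, "calls"))
    is_emergency = rng.random(n) < config.line_mix
    other_years = [y for y in config.years if y != config.test_year]
    year_p = np.array(
        [
            config.test_year_share if y == config.test_year else (1 - config.test_year_share) / len(other_years)
            for y in config.years
        ]
    )
    years = rng.choice(np.array(config.years), size=n, p=year_p)
    year_starts = pd.to_datetime(
        pd.DataFrame({"year": years, "month": np.ones(n, int), "day": np.ones(n, int)})
    )
    seconds = rng.integers(0, 365 * 24 * 3600, size=n)
    call_start = year_starts + pd.to_timedelta(seconds, unit="s")

    # --- planted stroke structure ----------------------------------------
    # stroke_prevalence is the rate of ground-truth positives; the registry
    # additionally carries SAH-typed and out-of-window entries on top.
    inflate = (1.0 - config.sah_fraction) * (1.0 - config.outside_window_fraction)
    p_registry = np.where(
        is_emergency, config.emergency_prevalence / inflate, config.stroke_prevalence / inflate
    )
    if np.any(p_registry > 1.0):
        raise ConfigurationError("prevalence / ((1-sah)(1-outside)) exceeds 1")
    in_registry = rng.random(n) < p_registry
    is_sah = in_registry & (rng.random(n) < config.sah_fraction)
    outside = in_registry & ~is_sah & (rng.random(n) < config.outside_window_fraction)
    truth = in_registry & ~is_sah & ~outside

    # --- demographics ------------------------------------------------------
    rng_demo = np.random.default_rng(_stage_seed(seed, "demographics"))
    ages = np.empty(n)
    for status, mask in (("stroke", in_registry), ("non_stroke", ~in_registry)):
        mean, sd = config.age_params[status]
        ages[mask] = _truncnorm_ages(mean, sd, config.age_bounds, int(mask.sum()), rng_demo)
    female = np.empty(n, dtype=bool)
    for status, mask in (("stroke", in_registry), ("non_stroke", ~in_registry)):
        female[mask] = rng_demo.random(int(mask.sum())) < config.female_fraction[status]

    # --- call-taker triage -------------------------------------------------
    missing_category = (
        np.random.default_rng(_stage_seed(seed, "category")).random(n)
        < config.missing_category_fraction
    )
    raw_label = simulate_calltaker(
        truth, config.calltaker_sensitivity, config.implied_fpr, _stage_seed(seed, "calltaker")
    )
    # Without a registered diagnostic category there is no recorded stroke
    # selection, hence no call-taker positive.
    positive = raw_label & ~missing_category
    rng_flags = np.random.default_rng(_stage_seed(seed, "flags"))
    u = rng_flags.random(n)
    # Negative calls: mostly neither flag; occasionally one of the two.
    category_selected = positive | (~positive & ~missing_category & (u < 0.02))
    ambulance = positive | (~positive & (u >= 0.02) & (u < 0.05))
    categories = np.where(
        missing_category,
        "",
        np.where(
            category_selected,
            "stroke",
            rng_flags.choice(np.array(_NON_STROKE_CATEGORIES), size=n),
        ),
    )

    call_ids = np.array([f"c{i:06d}" for i in range(n)])
    patient_ids = np.array([f"p{i:06d}" for i in range(n)])
    calls = pd.DataFrame(
        {
            "call_id": call_ids,
            "patient_id": patient_ids,
            "line": np.where(is_emergency, "emergency", "helpline"),
            "call_start": call_start,
            "age": np.round(ages, 1),
            "sex": np.where(female, "female", "male"),
            "diagnostic_category": categories,
            "stroke_category_selected": category_selected,
            "ambulance_dispatched_appropriate": ambulance,
            "planted_stroke": truth,
        }
    )

    # --- registry ----------------------------------------------------------
    rng_reg = np.random.default_rng(_stage_seed(seed, "registry"))
    reg_idx = np.flatnonzero(in_registry)
    lo, hi = config.onset_window_h
    offsets = rng_reg.uniform(lo, hi, size=reg_idx.size)
    out_mask = outside[reg_idx]
    n_out = int(out_mask.sum())
    if n_out:
        # Out-of-window onsets: half well before the window, half after it.
        before = rng_reg.random(n_out) < 0.5
        out_offsets = np.where(
            before, rng_reg.uniform(-120.0, -72.5, n_out), rng_reg.uniform(24.5, 48.0, n_out)
        )
        offsets[out_mask] = out_offsets
    types = rng_reg.choice(np.array(_STROKE_TYPES), size=reg_idx.size, p=_STROKE_TYPE_P)
    types[is_sah[reg_idx]] = "sah"
    registry = pd.DataFrame(
        {
            "patient_id": patient_ids[reg_idx],
            "onset_time": call_start.to_numpy()[reg_idx] + pd.to_timedelta(offsets, unit="h"),
            "stroke_type": types,
        }
    )

    # --- transcripts ---------------------------------------------------------
    transcripts = _generate_transcripts(config, in_registry, _stage_seed(seed, "transcripts"))
    transcripts = dict(zip(call_ids.tolist(), transcripts))

    truth_series = pd.Series(truth, index=call_ids, name="planted_stroke")
    return SyntheticCohort(calls, registry, transcripts, truth_series, config)


def _generate_transcripts(
    config: GeneratorConfig, is_stroke_like: np.ndarray, seed: int
) -> list[list[str]]:
    """Token sequences: Zipf background plus planted marker words.

    ``is_stroke_like`` marks the registry-linked calls (including SAH and
    out-of-window cases — clinically those are still stroke conversations).
    """
    n = is_stroke_like.shape[0]
    rng = np.random.default_rng(seed)
    lexicon = np.array([f"w{i:04d}" for i in range(config.vocab_size)], dtype=object)
    ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    probs = ranks ** (-config.zipf_exponent)
    probs /= probs.sum()
    cdf = np.cumsum(probs)

    lengths = config.doc_length_min + rng.poisson(
        max(config.doc_length_mean - config.doc_length_min, 0.0), size=n
    )
    total = int(lengths.sum())
    background = lexicon[np.searchsorted(cdf, rng.random(total))]
    if config.token_substitution_rate > 0:
        sub = rng.random(total) < config.token_substitution_rate
        background[sub] = lexicon[rng.integers(0, config.vocab_size, int(sub.sum()))]
    offsets = np.concatenate([[0], np.cumsum(lengths)])

    indicators = np.array(list(config.indicator_words), dtype=object)
    distractors = np.array(list(config.distractor_words), dtype=object)
    ind_rate = np.where(is_stroke_like, config.indicator_rate, config.indicator_background_rate)
    dis_rate = np.where(is_stroke_like, config.distractor_background_rate, config.distractor_rate)
    ind_hits = rng.random((n, indicators.size)) < ind_rate[:, None]
    dis_hits = rng.random((n, distractors.size)) < dis_rate[:, None]
    # An injected marker appears once, sometimes twice.
    ind_double = ind_hits & (rng.random((n, indicators.size)) < 0.3)
    dis_double = dis_hits & (rng.random((n, distractors.size)) < 0.3)

    docs: list[list[str]] = []
    for i in range(n):
        tokens = background[offsets[i] : offsets[i + 1]].tolist()
        tokens.extend(indicators[ind_hits[i]].tolist())
        tokens.extend(indicators[ind_double[i]].tolist())
        tokens.extend(distractors[dis_hits[i]].tolist())
        tokens.extend(distractors[dis_double[i]].tolist())
        perm = rng.permutation(len(tokens))
        docs.append([tokens[j] for j in perm])
    return docs
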
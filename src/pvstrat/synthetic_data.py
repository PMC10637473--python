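"""Generator for VigiBase-like synthetic ICSR datasets with planted signals.

Real spontaneous-reporting data cannot be redistributed, so this module
produces datasets with the same structure — many case reports, each with a
sex, one primary suspect drug and one or more coded reactions — and with
known ground truth for every drug-reaction association.

Generative model, per report:

1. sex ~ Categorical(sex_probs) over (male, female, unknown);
2. one primary drug ~ Categorical over the drug catalog marginals;
3. a reaction count k ~ Geometric(1 / mean) truncated to [1, n_terms],
   then k distinct reactions sampled without replacement with
   probabilities proportional to the reaction catalog weights;
4. for every planted signal (drug, reaction_pt, rho_male, rho_female)
   whose drug was drawn, the inclusion of reaction_pt is re-decided so
   that its marginal inclusion probability becomes clamp(rho * q), where
   q is its background inclusion probability — a multiplicative
   relative-reporting-rate model.

Under this model the asymptotic target of the information component for a
planted pair in its stratum is log2(rho), up to a small contamination term
of order f_drug * (rho - 1) in the reaction marginal (the drug's share
f_drug of the database is kept small in the default catalog precisely so
that this bias is negligible).  rho = 1 means no disproportionality;
rho = 0 means the pair never co-occurs.

Weighted sampling without replacement uses the exponential-race construction
(sort Exp(1)/w_j keys ascending, take the first k), which is equivalent to
successive sampling proportional to the remaining weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .icsr_model import (
    CaseReport,
    Dataset,
    ReactionTerm,
    Sex,
    default_term_map,
)

logger = logging.getLogger(__name__)

_SEX_VALUES = (Sex.MALE, Sex.FEMALE, Sex.UNKNOWN)

#: Draws used to calibrate background inclusion probabilities q_j.  The
#: calibration RNG seed is a fixed constant: q is a property of the
#: background sampling scheme, not of any one dataset.
_CALIBRATION_DRAWS = 200_000
_CALIBRATION_SEED = 987_654_321


@dataclass(frozen=True)
class PlantedSignal:
    """One ground-truth drug-reaction association with per-sex strength."""

    drug: str
    reaction_pt: str
    rho_male: float
    rho_female: float

    def rho(self, sex: Sex | str) -> float:
        sex = Sex(sex) if not isinstance(sex, Sex) else sex
        if sex is Sex.MALE:
            return self.rho_male
        if sex is Sex.FEMALE:
            return self.rho_female
        return 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic database.

    The defaults mirror the structure of the emulated study data: a drug of
    interest holding a small share of a 20-drug database, 40 preferred
    terms, a slight female reporting excess with a few percent of reports
    missing sex, and about 2.5 reactions per report.
    """

    n_reports: int
    drug_catalog: Mapping[str, float]
    reaction_catalog: Mapping[str, float]
    reactions_per_report_mean: float = 2.5
    sex_probs: tuple[float, float, float] = (0.45, 0.51, 0.04)
    signals: tuple[PlantedSignal, ...] = ()
    seed: int = 20211
    duplicate_rate: float = 0.0
    term_map: Mapping[str, ReactionTerm] | None = field(default=None, compare=False)

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ConfigError("n_reports must be >= 0")
        if not self.drug_catalog:
            raise ConfigError("drug_catalog must be non-empty")
        if not self.reaction_catalog:
            raise ConfigError("reaction_catalog must be non-empty")
        for name, cat in (
            ("drug_catalog", self.drug_catalog),
            ("reaction_catalog", self.reaction_catalog),
        ):
            for key, p in cat.items():
                if not 0.0 <= float(p) <= 1.0:
                    raise ConfigError(f"{name}[{key!r}] probability {p} not in [0, 1]")
            if sum(cat.values()) <= 0:
                raise ConfigError(f"{name} probabilities sum to zero")
        if self.reactions_per_report_mean < 1.0:
            raise ConfigError("reactions_per_report_mean must be >= 1")
        if len(self.sex_probs) != 3 or any(
            not 0.0 <= p <= 1.0 for p in self.sex_probs
        ):
            raise ConfigError("sex_probs must be three probabilities in [0, 1]")
        if abs(sum(self.sex_probs) - 1.0) > 1e-12:
            raise ConfigError("sex_probs must sum to 1 within 1e-12")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ConfigError("duplicate_rate must be in [0, 1)")
        seen = set()
        for sig in self.signals:
            if sig.drug not in self.drug_catalog:
                raise ConfigError(f"signals: drug {sig.drug!r} not in drug_catalog")
            if sig.reaction_pt not in self.reaction_catalog:
                raise ConfigError(
                    f"signals: reaction_pt {sig.reaction_pt!r} not in reaction_catalog"
                )
            if sig.rho_male < 0 or sig.rho_female < 0:
                raise ConfigError(f"signals: rho must be >= 0 for {sig.drug}/{sig.reaction_pt}")
            key = (sig.drug, sig.reaction_pt)
            if key in seen:
                raise ConfigError(f"signals: duplicate pair {key}")
            seen.add(key)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_reports": self.n_reports,
            "drug_catalog": dict(self.drug_catalog),
            "reaction_catalog": dict(self.reaction_catalog),
            "reactions_per_report_mean": self.reactions_per_report_mean,
            "sex_probs": list(self.sex_probs),
            "signals": [
                {
                    "drug": s.drug,
                    "reaction_pt": s.reaction_pt,
                    "rho_male": s.rho_male,
                    "rho_female": s.rho_female,
                }
                for s in self.signals
            ],
            "seed": self.seed,
            "duplicate_rate": self.duplicate_rate,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        known = {
            "n_reports",
            "drug_catalog",
            "reaction_catalog",
            "reactions_per_report_mean",
            "sex_probs",
            "signals",
            "seed",
            "duplicate_rate",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        for required in ("n_reports", "drug_catalog", "reaction_catalog"):
            if required not in data:
                raise ConfigError(f"missing config field: {required}")
        signals = tuple(
            PlantedSignal(
                drug=s["drug"],
                reaction_pt=s["reaction_pt"],
                rho_male=float(s.get("rho_male", 1.0)),
                rho_female=float(s.get("rho_female", 1.0)),
            )
            for s in data.get("signals", [])
        )
        cfg = cls(
            n_reports=int(data["n_reports"]),
            drug_catalog={str(k): float(v) for k, v in data["drug_catalog"].items()},
            reaction_catalog={
                str(k): float(v) for k, v in data["reaction_catalog"].items()
            },
            reactions_per_report_mean=float(data.get("reactions_per_report_mean", 2.5)),
            sex_probs=tuple(float(p) for p in data.get("sex_probs", (0.45, 0.51, 0.04))),
            signals=signals,
            seed=int(data.get("seed", 20211)),
            duplicate_rate=float(data.get("duplicate_rate", 0.0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# default catalogs


#: 20-drug background catalog.  The drug of interest holds a 1% share so
#: that signal contamination of the reaction marginals stays negligible.
DEFAULT_DRUG_CATALOG: dict[str, float] = {
    "dupilumab": 0.01,
    "ibuprofen": 0.09,
    "paracetamol": 0.09,
    "amoxicillin": 0.08,
    "metformin": 0.07,
    "atorvastatin": 0.07,
    "omeprazole": 0.06,
    "lisinopril": 0.06,
    "sertraline": 0.05,
    "salbutamol": 0.05,
    "prednisone": 0.05,
    "adalimumab": 0.05,
    "methotrexate": 0.05,
    "insulin glargine": 0.04,
    "warfarin": 0.04,
    "levothyroxine": 0.04,
    "amlodipine": 0.04,
    "simvastatin": 0.03,
    "azithromycin": 0.02,
    "ciprofloxacin": 0.01,
}

#: 40-PT background catalog matching the bundled PT -> SOC map: a handful of
#: very common reactions and a long tail of rare ones.
DEFAULT_REACTION_CATALOG: dict[str, float] = {
    "headache": 0.080,
    "nausea": 0.075,
    "nasopharyngitis": 0.060,
    "injection_site_reaction": 0.055,
    "arthralgia": 0.055,
    "conjunctivitis": 0.040,
    "dry_eye": 0.040,
    "blepharitis": 0.040,
    "dry_skin": 0.040,
    "alopecia": 0.035,
    "eye_infection": 0.030,
    "staphylococcal_infection": 0.030,
    "acne": 0.030,
    "psoriasis": 0.025,
    "cataract": 0.025,
    "back_disorder": 0.025,
    "streptococcal_pharyngitis": 0.020,
    "erysipelas": 0.020,
    "alopecia_areata": 0.020,
    "hyposmia": 0.015,
    "pulmonary_congestion": 0.015,
    "episcleritis": 0.015,
    "vitiligo": 0.015,
    "immune_system_disorder": 0.015,
    "cutaneous_t_cell_lymphoma_stage_i": 0.015,
    "cutaneous_t_cell_lymphoma_stage_ii": 0.015,
    "cutaneous_t_cell_lymphoma_stage_iii": 0.015,
    "cutaneous_t_cell_lymphoma_stage_iv": 0.015,
    "erythema_nodosum": 0.012,
    "corneal_erosion": 0.012,
    "atopic_keratoconjunctivitis": 0.012,
    "keratoconus": 0.012,
    "acanthosis_nigricans": 0.010,
    "acarodermatitis": 0.010,
    "alopecia_totalis": 0.010,
    "knee_operation": 0.010,
    "hypereosinophilic_syndrome": 0.010,
    "seronegative_arthritis": 0.008,
    "peak_expiratory_flow_rate_decreased": 0.008,
    "seminoma": 0.006,
}


def default_config(
    n_reports: int = 100_000,
    seed: int = 20211,
    signals: Sequence[PlantedSignal] = (),
    **overrides,
) -> SimulationConfig:
    """The standard study-like configuration: 20 drugs, 40 PTs, female excess."""
    cfg = SimulationConfig(
        n_reports=n_reports,
        drug_catalog=dict(DEFAULT_DRUG_CATALOG),
        reaction_catalog=dict(DEFAULT_REACTION_CATALOG),
        signals=tuple(signals),
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# background inclusion calibration


@lru_cache(maxsize=8)
def _background_inclusion_probs(
    weights: tuple[float, ...], mean_k: float
) -> np.ndarray:
    """Monte-Carlo estimate of q_j = P(PT j included) under the background draw.

    No closed form exists for inclusion probabilities of weighted sampling
    without replacement with a random sample size, so q is calibrated once
    per (weights, mean) pair with a fixed-seed RNG and cached.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    membership = _draw_background(rng, _CALIBRATION_DRAWS, np.array(weights), mean_k)
    return membership.mean(axis=0)


def _draw_background(
    rng: np.random.Generator, n: int, weights: np.ndarray, mean_k: float
) -> np.ndarray:
    """Boolean (n, n_terms) background reaction membership matrix."""
    m = len(weights)
    k = np.minimum(rng.geometric(1.0 / mean_k, size=n), m)
    with np.errstate(divide="ignore"):
        keys = rng.exponential(1.0, size=(n, m)) / np.where(weights > 0, weights, np.nan)
    keys = np.where(np.isnan(keys), np.inf, keys)
    order = np.argsort(keys, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(m), (n, m)).copy(), axis=1
    )
    return ranks < k[:, None]


# ---------------------------------------------------------------------------
# generation


def generate(config: SimulationConfig) -> Dataset:
    """Draw one synthetic dataset; fully determined by ``config.seed``."""
    config.validate()
    n = config.n_reports
    term_map = _resolve_term_map(config)
    if n == 0:
        return Dataset([], dict(term_map))

    rng = np.random.default_rng(config.seed)
    drug_names = list(config.drug_catalog)
    p_drug = np.array([config.drug_catalog[d] for d in drug_names], dtype=float)
    p_drug = p_drug / p_drug.sum()
    pt_names = list(config.reaction_catalog)
    w_pt = np.array([config.reaction_catalog[p] for p in pt_names], dtype=float)
    pt_pos = {p: j for j, p in enumerate(pt_names)}

    sex_codes = rng.choice(3, size=n, p=np.asarray(config.sex_probs, dtype=float))
    drug_idx = rng.choice(len(drug_names), size=n, p=p_drug)
    membership = _draw_background(
        rng, n, w_pt / w_pt.sum(), config.reactions_per_report_mean
    )

    needs_q = any(
        r > 1.0 for s in config.signals for r in (s.rho_male, s.rho_female)
    )
    q = (
        _background_inclusion_probs(
            tuple(w_pt / w_pt.sum()), config.reactions_per_report_mean
        )
        if needs_q
        else None
    )

    n_clamped = 0
    zero_rho: list[tuple[np.ndarray, int]] = []  # (row mask, pt column) never allowed
    for sig in config.signals:
        j = pt_pos[sig.reaction_pt]
        d = drug_names.index(sig.drug)
        for sex_code, rho in ((0, sig.rho_male), (1, sig.rho_female)):
            if rho == 1.0:
                continue
            rows = (drug_idx == d) & (sex_codes == sex_code)
            u = rng.random(n)  # drawn unconditionally to keep the stream aligned
            if rho < 1.0:
                drop = rows & membership[:, j] & (u >= rho)
                membership[drop, j] = False
                if rho == 0.0:
                    zero_rho.append((rows, j))
            else:
                qj = float(q[j])
                target = qj * rho
                if target > 1.0:
                    n_clamped += int(rows.sum())
                    target = 1.0
                p_add = (target - qj) / (1.0 - qj) if qj < 1.0 else 0.0
                add = rows & ~membership[:, j] & (u < p_add)
                membership[add, j] = True
    if n_clamped:
        logger.warning(
            "signal inclusion probability exceeded 1 and was clamped on %d reports",
            n_clamped,
        )

    # guarantee the non-empty-reactions invariant: a rho < 1 thinning can
    # strip the sole reaction from a report; backfill with the most common
    # background PT that is not excluded for that report
    empty = ~membership.any(axis=1)
    if empty.any():
        for i in np.flatnonzero(empty):
            banned = {j for rows, j in zero_rho if rows[i]}
            for j in np.argsort(-w_pt):
                if j not in banned:
                    membership[i, j] = True
                    break

    reports = _build_reports(
        n, sex_codes, drug_idx, membership, drug_names, pt_names
    )

    if config.duplicate_rate > 0.0:
        n_dup = int(round(config.duplicate_rate * n))
        if n_dup:
            dup_idx = rng.choice(n, size=n_dup, replace=False)
            reports = reports + [reports[i] for i in dup_idx]

    logger.info(
        "generated %d reports (%d drugs, %d PTs, %d planted signals)",
        len(reports),
        len(drug_names),
        len(pt_names),
        len(config.signals),
    )
    return Dataset(reports, dict(term_map))


def _resolve_term_map(config: SimulationConfig) -> dict[str, ReactionTerm]:
    if config.term_map is not None:
        return dict(config.term_map)
    bundled = default_term_map()
    terms = {}
    for pt in config.reaction_catalog:
        terms[pt] = bundled.get(
            pt, ReactionTerm(pt, pt, "SOC_SYN", "Synthetic disorders")
        )
    return terms


def _build_reports(
    n: int,
    sex_codes: np.ndarray,
    drug_idx: np.ndarray,
    membership: np.ndarray,
    drug_names: list[str],
    pt_names: list[str],
) -> list[CaseReport]:
    pts_arr = np.array(pt_names, dtype=object)
    counts = membership.sum(axis=1)
    rows, cols = np.nonzero(membership)
    boundaries = np.cumsum(counts)[:-1]
    per_row = np.split(pts_arr[cols], boundaries)
    width = max(7, len(str(max(n - 1, 0))))
    return [
        CaseReport(
            case_id=f"R{i:0{width}d}",
            sex=_SEX_VALUES[sex_codes[i]],
            drugs=frozenset((drug_names[drug_idx[i]],)),
            reactions=frozenset(per_row[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# ground truth


def true_ic(
    config: SimulationConfig, drug: str, reaction_pt: str, sex: Sex | str
) -> float:
    """log2 of the planted relative reporting rate for the pair in a sex stratum.

    This is the asymptotic target of the IC estimator under the generator;
    unplanted pairs return 0.0 and rho = 0 returns -inf.
    """
    if drug not in config.drug_catalog:
        raise KeyError(f"drug {drug!r} not in drug_catalog")
    if reaction_pt not in config.reaction_catalog:
        raise KeyError(f"reaction_pt {reaction_pt!r} not in reaction_catalog")
    sex = Sex(sex) if not isinstance(sex, Sex) else sex
    rho = 1.0
    for sig in config.signals:
        if sig.drug == drug and sig.reaction_pt == reaction_pt:
            rho = sig.rho(sex)
            break
    if rho == 0.0:
        return float("-inf")
    return float(np.log2(rho))


def truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth table for all planted signals (one row per pair)."""
    rows = [
        {
            "drug": s.drug,
            "reaction_pt": s.reaction_pt,
            "rho_male": s.rho_male,
            "rho_female": s.rho_female,
            "true_ic_male": true_ic(config, s.drug, s.reaction_pt, Sex.MALE),
            "true_ic_female": true_ic(config, s.drug, s.reaction_pt, Sex.FEMALE),
        }
        for s in config.signals
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "drug",
            "reaction_pt",
            "rho_male",
            "rho_female",
            "true_ic_male",
            "true_ic_female",
        ],
    )
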
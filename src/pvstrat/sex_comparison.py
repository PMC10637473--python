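"""Male/female stratified comparison of drug-reaction disproportionality.

For one drug of interest, every reaction observed with it in either sex
stratum gets a row holding the male and female disproportionality results
side by side plus a sex-pattern label:

    male_only        signal in males, pair never reported in females
    female_only      symmetric
    male_stronger    signal in males and either no signal in females or the
                     male IC025 exceeds the female IC975 (interval separation)
    female_stronger  symmetric
    both_equal       signal in both sexes with overlapping credibility
                     intervals
    neither          everything else

The interval-separation rule is a deliberately conservative operational
definition of "stronger association": it only separates the sexes when the
95% credibility intervals do not overlap (or one sex shows no signal at
all).  The module also computes database-level summary statistics for the
drug: how many reports carry sex information, per-sex report counts and
the female-to-male reporting ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .contingency import get_index
from .disproportionality import DisproportionalityResult, evaluate_pair
from .errors import UndefinedStratumError
from .icsr_model import Dataset, Sex

logger = logging.getLogger(__name__)

PATTERNS = (
    "male_only",
    "female_only",
    "male_stronger",
    "female_stronger",
    "both_equal",
    "neither",
)


@dataclass(frozen=True)
class SexComparisonRow:
    """One reaction's male and female results plus the sex-pattern label."""

    reaction_pt: str
    soc: str
    male: DisproportionalityResult
    female: DisproportionalityResult
    pattern: str


def classify_pattern(
    male: DisproportionalityResult, female: DisproportionalityResult
) -> str:
    """Assign exactly one sex-pattern label to a (male, female) result pair.

    Antisymmetric by construction: swapping the arguments swaps
    male_only <-> female_only and male_stronger <-> female_stronger while
    fixing both_equal and neither.
    """
    if male.is_signal and female.is_na:
        return "male_only"
    if female.is_signal and male.is_na:
        return "female_only"
    if male.is_na or female.is_na:
        return "neither"
    if male.is_signal and (not female.is_signal or male.ic025 > female.ic975):
        return "male_stronger"
    if female.is_signal and (not male.is_signal or female.ic025 > male.ic975):
        return "female_stronger"
    if male.is_signal and female.is_signal:
        return "both_equal"
    return "neither"


def run_comparison(
    dataset: Dataset,
    drug: str,
    level: float = 0.95,
    interval_method: str = "gamma",
) -> list[SexComparisonRow]:
    """Full stratified comparison for one drug across all its reactions.

    One row per PT observed with the drug in either sex stratum, sorted by
    SOC code then PT code.  The dataset must be deduplicated.  An absent
    drug yields an empty list with a warning.
    """
    idx = get_index(dataset)
    if drug not in idx.drug_pos:
        logger.warning("drug %r not present in dataset; empty comparison", drug)
        return []
    d_col = idx.D[:, idx.drug_pos[drug]]
    male_mask = idx.stratum_mask("male")
    female_mask = idx.stratum_mask("female")
    with_drug = d_col & (male_mask | female_mask)
    observed_pts = sorted(
        {pt for i in with_drug.nonzero()[0] for pt in dataset.reports[i].reactions}
    )
    def _evaluate(pt: str, stratum: str) -> DisproportionalityResult:
        # an entirely empty stratum (e.g. no female reports at all) renders
        # as NA rather than aborting the whole comparison
        try:
            return evaluate_pair(dataset, drug, pt, stratum, level, interval_method)
        except UndefinedStratumError:
            return DisproportionalityResult.na()

    rows = []
    for pt in observed_pts:
        male = _evaluate(pt, "male")
        female = _evaluate(pt, "female")
        rows.append(
            SexComparisonRow(
                reaction_pt=pt,
                soc=dataset.map_to_soc(pt).soc_code,
                male=male,
                female=female,
                pattern=classify_pattern(male, female),
            )
        )
    rows.sort(key=lambda r: (r.soc, r.reaction_pt))
    return rows


def comparison_frame(rows: list[SexComparisonRow]) -> pd.DataFrame:
    """Publication-table layout: PT, SOC, per-sex IC triples, pattern."""
    return pd.DataFrame(
        [
            {
                "reaction_pt": r.reaction_pt,
                "soc": r.soc,
                "male_ic": r.male.ic,
                "male_ic025": r.male.ic025,
                "male_ic975": r.male.ic975,
                "female_ic": r.female.ic,
                "female_ic025": r.female.ic025,
                "female_ic975": r.female.ic975,
                "pattern": r.pattern,
            }
            for r in rows
        ],
        columns=[
            "reaction_pt",
            "soc",
            "male_ic",
            "male_ic025",
            "male_ic975",
            "female_ic",
            "female_ic025",
            "female_ic975",
            "pattern",
        ],
    )


def heatmap_frame(rows: list[SexComparisonRow]) -> pd.DataFrame:
    """Long-form PT x sex -> IC table feeding a heat map."""
    records = []
    for r in rows:
        records.append({"reaction_pt": r.reaction_pt, "sex": "male", "ic": r.male.ic})
        records.append(
            {"reaction_pt": r.reaction_pt, "sex": "female", "ic": r.female.ic}
        )
    return pd.DataFrame(records, columns=["reaction_pt", "sex", "ic"])


def forest_frame(rows: list[SexComparisonRow]) -> pd.DataFrame:
    """Per-sex IC point and bounds feeding a forest plot."""
    records = []
    for r in rows:
        for sex, res in (("male", r.male), ("female", r.female)):
            records.append(
                {
                    "reaction_pt": r.reaction_pt,
                    "sex": sex,
                    "ic": res.ic,
                    "ic025": res.ic025,
                    "ic975": res.ic975,
                }
            )
    return pd.DataFrame(records, columns=["reaction_pt", "sex", "ic", "ic025", "ic975"])


# ---------------------------------------------------------------------------
# summary statistics


@dataclass(frozen=True)
class SummaryStats:
    """Sex composition of the counting units associated with one drug.

    Percentages and the ratio are recomputed from the stored counts on each
    access, so displayed values can never drift from the counts.

    ``n_with_sex`` is stored separately rather than derived as
    ``n_female + n_male``: when the counting unit is the distinct report the
    two coincide, but published summaries sometimes count entities (e.g.
    ADR terms) that can be reported in both sexes, making the per-sex
    counts overlap.
    """

    n_reports_total: int
    n_female: int
    n_male: int
    n_with_sex: int

    def __post_init__(self) -> None:
        if self.n_with_sex < max(self.n_female, self.n_male):
            raise ValueError("n_with_sex cannot be below either per-sex count")

    @property
    def pct_with_sex(self) -> float:
        return 100.0 * self.n_with_sex / self.n_reports_total

    @property
    def pct_female_of_sexed(self) -> float:
        return 100.0 * self.n_female / self.n_with_sex

    @property
    def pct_male_of_sexed(self) -> float:
        return 100.0 * self.n_male / self.n_with_sex

    @property
    def f_to_m_ratio(self) -> float:
        if self.n_male == 0:
            return math.nan
        return self.n_female / self.n_male

    @classmethod
    def from_counts(
        cls, total: int, female: int, male: int, sexed: int | None = None
    ) -> "SummaryStats":
        """Build from counts; ``sexed`` defaults to disjoint female + male."""
        return cls(
            n_reports_total=total,
            n_female=female,
            n_male=male,
            n_with_sex=sexed if sexed is not None else female + male,
        )

    def display(self) -> dict:
        """Rounded values for reporting: percentages to 1 dp, ratio to 2 dp."""
        ratio = self.f_to_m_ratio
        return {
            "n_reports_total": self.n_reports_total,
            "n_with_sex": self.n_with_sex,
            "pct_with_sex": round(self.pct_with_sex, 1),
            "n_female": self.n_female,
            "n_male": self.n_male,
            "pct_female_of_sexed": round(self.pct_female_of_sexed, 1),
            "pct_male_of_sexed": round(self.pct_male_of_sexed, 1),
            "f_to_m_ratio": None if math.isnan(ratio) else round(ratio, 2),
        }


def summary_statistics(dataset: Dataset, drug: str) -> SummaryStats:
    """Sex composition of the deduplicated reports mentioning the drug."""
    reports = [r for r in dataset.reports if drug in r.drugs]
    n_female = sum(1 for r in reports if r.sex is Sex.FEMALE)
    n_male = sum(1 for r in reports if r.sex is Sex.MALE)
    return SummaryStats(
        n_reports_total=len(reports),
        n_female=n_female,
        n_male=n_male,
        n_with_sex=n_female + n_male,
    )
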
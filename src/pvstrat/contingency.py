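"""Per-stratum 2x2 sufficient statistics for drug-reaction pairs.

For a drug D and reaction R in a stratum (male, female, or all reports),
the sufficient statistics are report-level counts:

    n_observed  distinct reports mentioning both D and R
    n_drug      distinct reports mentioning D
    n_reaction  distinct reports mentioning R
    n_total     distinct reports in the stratum

and the independence expectation

    n_expected = n_drug * n_reaction / n_total.

Stratified analyses are fully within-stratum: all four counts are
restricted to reports of that sex, which keeps the male and female
disproportionality estimates independent subgroup analyses.  Sex-unknown
reports contribute only to the ``all`` stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedStratumError
from .icsr_model import Dataset, Sex

STRATA = ("male", "female", "all")

_SEX_CODE = {Sex.MALE: 0, Sex.FEMALE: 1, Sex.UNKNOWN: 2}


@dataclass(frozen=True)
class StratumCounts:
    """The 2x2 sufficient statistics for one drug-reaction pair in one stratum."""

    stratum: str
    n_observed: int
    n_drug: int
    n_reaction: int
    n_total: int

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if not (
            0
            <= self.n_observed
            <= min(self.n_drug, self.n_reaction)
            <= self.n_total
        ):
            raise ValueError(f"inconsistent counts: {self}")
        if self.cells()[3] < 0:
            raise ValueError(f"negative complement cell: {self}")

    def cells(self) -> tuple[int, int, int, int]:
        """The 2x2 table (a, b, c, d); the four cells sum to n_total."""
        a = self.n_observed
        b = self.n_drug - a
        c = self.n_reaction - a
        d = self.n_total - self.n_drug - self.n_reaction + a
        return a, b, c, d


class _Index:
    """Boolean report-by-drug and report-by-PT membership matrices.

    Built once per dataset and cached on it; all counting reduces to masked
    column sums and one matrix product for the all-pairs table.
    """

    def __init__(self, dataset: Dataset):
        reports = dataset.reports
        n = len(reports)
        self.n = n
        self.sex = np.fromiter(
            (_SEX_CODE[r.sex] for r in reports), dtype=np.int8, count=n
        )
        self.drugs = sorted({d for r in reports for d in r.drugs})
        self.pts = sorted({pt for r in reports for pt in r.reactions})
        drug_pos = {d: j for j, d in enumerate(self.drugs)}
        pt_pos = {p: j for j, p in enumerate(self.pts)}
        self.drug_pos = drug_pos
        self.pt_pos = pt_pos
        self.D = np.zeros((n, len(self.drugs)), dtype=bool)
        self.R = np.zeros((n, len(self.pts)), dtype=bool)
        for i, r in enumerate(reports):
            for d in r.drugs:
                self.D[i, drug_pos[d]] = True
            for pt in r.reactions:
                self.R[i, pt_pos[pt]] = True

    def stratum_mask(self, stratum: str) -> np.ndarray:
        if stratum == "all":
            return np.ones(self.n, dtype=bool)
        if stratum == "male":
            return self.sex == 0
        if stratum == "female":
            return self.sex == 1
        raise ValueError(f"unknown stratum {stratum!r}")


def get_index(dataset: Dataset) -> _Index:
    if dataset._index is None:
        dataset._index = _Index(dataset)
    return dataset._index


def count_stratum(
    dataset: Dataset, drug: str, reaction_pt: str, stratum: str
) -> StratumCounts:
    """Count the 2x2 sufficient statistics for one pair in one stratum.

    The dataset is assumed deduplicated.  A drug or PT absent from the
    dataset yields zero marginal counts rather than an error.
    """
    idx = get_index(dataset)
    mask = idx.stratum_mask(stratum)
    n_total = int(mask.sum())
    dj = idx.drug_pos.get(drug)
    rj = idx.pt_pos.get(reaction_pt)
    d_col = idx.D[:, dj] if dj is not None else np.zeros(idx.n, dtype=bool)
    r_col = idx.R[:, rj] if rj is not None else np.zeros(idx.n, dtype=bool)
    return StratumCounts(
        stratum=stratum,
        n_observed=int((d_col & r_col & mask).sum()),
        n_drug=int((d_col & mask).sum()),
        n_reaction=int((r_col & mask).sum()),
        n_total=n_total,
    )


def expected_count(counts: StratumCounts) -> float:
    """Independence expectation n_drug * n_reaction / n_total, unrounded."""
    if counts.n_total == 0:
        raise UndefinedStratumError(
            f"stratum {counts.stratum!r} contains no reports"
        )
    return counts.n_drug * counts.n_reaction / counts.n_total


def pair_counts(
    dataset: Dataset,
    drugs: Iterable[str] | None = None,
    reaction_pts: Iterable[str] | None = None,
    strata: Sequence[str] = STRATA,
) -> pd.DataFrame:
    """All-pairs count table, one row per (drug, reaction_pt, stratum).

    Vectorised over pairs: per stratum the observed-count block is a single
    boolean matrix product.  ``n_expected`` is NaN for an empty stratum.
    """
    idx = get_index(dataset)
    drug_list = list(drugs) if drugs is not None else idx.drugs
    pt_list = list(reaction_pts) if reaction_pts is not None else idx.pts
    d_cols = [idx.drug_pos.get(d) for d in drug_list]
    r_cols = [idx.pt_pos.get(p) for p in pt_list]

    frames = []
    for stratum in strata:
        mask = idx.stratum_mask(stratum)
        D = idx.D[mask]
        R = idx.R[mask]
        n_total = int(mask.sum())
        n_drug_all = D.sum(axis=0)
        n_react_all = R.sum(axis=0)
        obs = D.astype(np.int64).T @ R.astype(np.int64)  # (n_drugs, n_pts)

        def _take(vec: np.ndarray, cols: list) -> np.ndarray:
            return np.array([int(vec[j]) if j is not None else 0 for j in cols])

        nd = _take(n_drug_all, d_cols)
        nr = _take(n_react_all, r_cols)
        n_obs = np.zeros((len(d_cols), len(r_cols)), dtype=np.int64)
        for i, dj in enumerate(d_cols):
            if dj is None:
                continue
            for k, rj in enumerate(r_cols):
                if rj is not None:
                    n_obs[i, k] = obs[dj, rj]
        di, ri = np.meshgrid(np.arange(len(d_cols)), np.arange(len(r_cols)), indexing="ij")
        frame = pd.DataFrame(
            {
                "drug": np.array(drug_list)[di.ravel()],
                "reaction_pt": np.array(pt_list)[ri.ravel()],
                "stratum": stratum,
                "n_observed": n_obs.ravel(),
                "n_drug": nd[di.ravel()],
                "n_reaction": nr[ri.ravel()],
                "n_total": n_total,
            }
        )
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["n_expected"] = np.where(
            out["n_total"] > 0,
            out["n_drug"] * out["n_reaction"] / out["n_total"].replace(0, np.nan),
            np.nan,
        )
    return out
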
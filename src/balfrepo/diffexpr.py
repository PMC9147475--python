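"""Differential expression of label-free proteomic intensities.

The quantification table holds protein-level label-free intensities for two
groups of samples (case = COPD, control = healthy). Proteins are called
differentially expressed (DE) when they pass both an absolute fold-change
filter (linear ratio >= ``fc_threshold`` in either direction) and a raw
significance filter (Welch's t on log2 intensities, p < ``alpha``). No
multiple-testing correction is applied by default; this mirrors common
practice in small-cohort discovery proteomics and is deliberately
conservative about nothing — see the methods note for the caveats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

UP = "up_in_case"
DOWN = "down_in_case"
NS = "not_significant"

CASE = "case"
CONTROL = "control"


class AlbuminError(ValueError):
    """Raised when albumin-based normalization is impossible."""


@dataclass
class QuantTable:
    """Protein x sample intensity matrix with group labels.

    Parameters
    ----------
    intensities
        DataFrame indexed by protein ID, columns are sample IDs,
        values are non-negative label-free intensities.
    groups
        Series mapping sample ID -> group label (``"case"`` / ``"control"``).
    albumin_id
        Row ID of the albumin entry used for per-sample normalization,
        or None if the table carries no albumin reference.
    """

    intensities: pd.DataFrame
    groups: pd.Series
    albumin_id: str | None = None

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.intensities.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in (CASE, CONTROL):
            if (self.groups == g).sum() < 2:
                raise ValueError(f"need >=2 samples in group {g!r}")
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate protein IDs")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities")

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CONTROL])

    def to_tsv(self, quant_path: str | Path, samples_path: str | Path) -> None:
        self.intensities.rename_axis("protein_id").to_csv(quant_path, sep="\t")
        pd.DataFrame(
            {"sample_id": self.groups.index, "group": self.groups.to_numpy()}
        ).to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        quant_path: str | Path,
        samples_path: str | Path,
        albumin_id: str | None = None,
    ) -> "QuantTable":
        intens = pd.read_csv(quant_path, sep="\t", index_col="protein_id")
        samples = pd.read_csv(samples_path, sep="\t")
        groups = pd.Series(
            samples["group"].to_numpy(), index=samples["sample_id"], name="group"
        )
        return cls(intens, groups, albumin_id=albumin_id)


@dataclass
class DifferentialTable:
    """Per-protein differential expression results.

    ``table`` columns: mean_case, mean_control, fold_change (linear
    case/control ratio), log2_fc, p_value, direction. ``excluded`` lists
    proteins dropped from the ratio because a group mean was zero.
    """

    table: pd.DataFrame
    alpha: float
    fc_threshold: float
    excluded: list[str] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return int((self.table["direction"] != NS).sum())

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == UP).sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == DOWN).sum())

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != NS]

    def directions(self) -> dict[str, str]:
        """Protein -> direction for significant proteins only."""
        sig = self.significant
        return dict(zip(sig.index, sig["direction"]))

    def summary(self) -> dict[str, int]:
        return {
            "total": self.n_significant,
            "up_in_case": self.n_up,
            "down_in_case": self.n_down,
        }

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("protein_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, alpha: float = 0.05, fc_threshold: float = 1.5
    ) -> "DifferentialTable":
        table = pd.read_csv(path, sep="\t", index_col="protein_id")
        return cls(table, alpha=alpha, fc_threshold=fc_threshold)


def normalize_to_albumin(qt: QuantTable) -> QuantTable:
    """Divide each sample column by that sample's albumin intensity.

    Albumin in the lavage fluid is used as a per-sample recovery
    reference: dividing by it removes sample-to-sample dilution
    introduced by variable lavage return volumes. After normalization
    the albumin row is identically 1.
    """
    if qt.albumin_id is None or qt.albumin_id not in qt.intensities.index:
        raise AlbuminError("quantification table has no albumin row")
    alb = qt.intensities.loc[qt.albumin_id]
    zero = alb[alb <= 0]
    if len(zero):
        raise AlbuminError(
            f"albumin intensity missing/zero in sample(s): {list(zero.index)}"
        )
    return QuantTable(qt.intensities / alb, qt.groups.copy(), albumin_id=qt.albumin_id)


def differential_test(
    qt: QuantTable,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    min_evidence: pd.Series | None = None,
    min_evidence_threshold: int = 1,
) -> DifferentialTable:
    """Two-group differential test with fold-change and p-value filters.

    Fold change is the ratio of linear-scale group means (case/control);
    the test is Welch's unequal-variance t on log2-transformed
    intensities. A protein is significant iff ``|log2_fc| >=
    log2(fc_threshold)`` and ``p < alpha``; direction follows the sign
    of log2_fc.

    Proteins with a zero group mean cannot be assigned a finite ratio;
    they are excluded from calling and listed in ``excluded``.

    ``min_evidence`` optionally maps protein -> peptide-evidence count;
    proteins below ``min_evidence_threshold`` are dropped up front
    (strict two-peptide mode uses threshold 2; the default, pragmatic
    mode keeps every identified protein).
    """
    intens = qt.intensities
    if min_evidence is not None:
        keep = min_evidence.reindex(intens.index).fillna(0) >= min_evidence_threshold
        intens = intens.loc[keep]

    case = intens[qt.case_samples].to_numpy(dtype=float)
    ctrl = intens[qt.control_samples].to_numpy(dtype=float)

    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    valid = (mean_case > 0) & (mean_ctrl > 0)
    excluded = list(intens.index[~valid])
    if excluded:
        warnings.warn(
            f"{len(excluded)} protein(s) with a zero group mean excluded from "
            "fold-change calling",
            stacklevel=2,
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_case / mean_ctrl
        log2_fc = np.log2(fc)
        # log2 for the test; zero intensities only arise alongside an
        # excluded protein or sporadic missingness -> -inf clipped out
        lcase = np.log2(np.clip(case, 1e-12, None))
        lctrl = np.log2(np.clip(ctrl, 1e-12, None))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance rows yield NaN, handled below
        _, pvals = stats.ttest_ind(lcase, lctrl, axis=1, equal_var=False)
    # degenerate rows (both groups constant): no evidence against the null
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    log2_cut = np.log2(fc_threshold)
    sig = valid & (np.abs(log2_fc) >= log2_cut) & (pvals < alpha)
    direction = np.where(sig, np.where(log2_fc > 0, UP, DOWN), NS)

    table = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "fold_change": np.where(valid, fc, np.nan),
            "log2_fc": np.where(valid, log2_fc, np.nan),
            "p_value": pvals,
            "direction": direction,
        },
        index=intens.index,
    )
    return DifferentialTable(
        table, alpha=alpha, fc_threshold=fc_threshold, excluded=excluded
    )
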
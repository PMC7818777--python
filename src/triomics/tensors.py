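"""Three-way tensor construction and case-control within-normalization.

Long-format measurements are binned into an ``OmicsTensor`` with modes
(subjects i, features j, timepoints k), where x_ijk is the value of omics
feature j in subject i at binned timepoint k (months before seroconversion,
MBSC).  Subjects observed at fewer than 3 of the 5 timepoints are split off
into a validation pool; within each matched case-control set the set mean is
subtracted at every feature and timepoint, so that values express divergence
of a case from its matched controls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinSpec",
    "OmicsTensor",
    "DEFAULT_BIN_SPEC",
    "bin_to_tensor",
    "filter_and_split",
    "within_normalize",
    "write_tensor_bundle",
    "read_tensor_bundle",
]


@dataclass(frozen=True)
class BinSpec:
    """Ordered (label, lower_mbsc, upper_mbsc) intervals.

    Bins are closed-left/open-right on MBSC; the final (largest-MBSC) bin is
    closed on both ends so the printed upper boundary is kept.
    """

    intervals: tuple[tuple[int, float, float], ...]

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda x: x[1])
        for (_, lo, hi) in ivs:
            if hi <= lo:
                raise ValueError("bin interval upper bound must exceed lower bound")
        for (_, _, hi_prev), (_, lo, _) in zip(ivs, ivs[1:]):
            if lo < hi_prev:
                raise ValueError("bin intervals overlap")

    def assign(self, mbsc: np.ndarray) -> np.ndarray:
        """Map MBSC values to bin labels; unassigned values get -1."""
        mbsc = np.asarray(mbsc, dtype=float)
        out = np.full(mbsc.shape, -1, dtype=int)
        upper_most = max(hi for _, _, hi in self.intervals)
        for label, lo, hi in self.intervals:
            inside = (mbsc >= lo) & ((mbsc < hi) | ((hi == upper_most) & (mbsc == hi)))
            out[inside] = label
        return out

    @property
    def labels_desc(self) -> list[int]:
        """Bin labels in descending MBSC order (earliest visit first)."""
        return [lab for lab, _, _ in sorted(self.intervals, key=lambda x: -x[1])]


#: 3-month visit bins: timepoints 0, 3, 6, 9, 12 MBSC cover
#: 1-1.5, 1.5-4.5, 4.5-7.5, 7.5-10.5 and 10.5-13.5 months before SC.
DEFAULT_BIN_SPEC = BinSpec(
    intervals=(
        (0, 1.0, 1.5),
        (3, 1.5, 4.5),
        (6, 4.5, 7.5),
        (9, 7.5, 10.5),
        (12, 10.5, 13.5),
    )
)


@dataclass
class OmicsTensor:
    """A 3-way array (subjects x features x timepoints) with observation mask.

    ``mask`` is True where the value came from data; after imputation the
    filled cells stay False so imputed cells remain identifiable.  Timepoint
    labels are MBSC values in strictly decreasing order (12 -> 0).
    """

    values: np.ndarray
    mask: np.ndarray
    subject_ids: list[str]
    feature_ids: list[str]
    timepoints: list[int]
    block: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (
            len(self.subject_ids),
            len(self.feature_ids),
            len(self.timepoints),
        ):
            raise ValueError("axis labels do not match array shape")
        if any(a <= b for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly decreasing in MBSC")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def subject_observed_timepoints(self) -> np.ndarray:
        """Per subject, the number of timepoints with any observed feature."""
        return self.mask.any(axis=1).sum(axis=1)

    def subset_subjects(self, keep: list[str]) -> "OmicsTensor":
        idx = [self.subject_ids.index(s) for s in keep]
        return replace(
            self,
            values=self.values[idx].copy(),
            mask=self.mask[idx].copy(),
            subject_ids=list(keep),
        )


def bin_to_tensor(
    measurements: pd.DataFrame,
    bin_spec: BinSpec = DEFAULT_BIN_SPEC,
    block: str | None = None,
) -> OmicsTensor:
    """Bin long-format measurements of one omics block into an OmicsTensor.

    Each measurement is assigned to the unique bin containing its MBSC value;
    multiple values for the same subject x feature x bin are averaged.
    Measurements outside every bin are dropped (the count is logged).
    """
    df = measurements
    if block is not None:
        df = df[df["block"] == block]
    else:
        blocks = df["block"].unique()
        if len(blocks) != 1:
            raise ValueError("measurements span multiple blocks; pass block=")
        block = str(blocks[0])
    if df.empty:
        raise ValueError(f"no measurements for block {block!r}")

    labels = bin_spec.assign(df["months_before_sc"].to_numpy())
    n_excluded = int((labels == -1).sum())
    if n_excluded:
        logger.warning(
            "block %s: %d measurements outside bin range excluded", block, n_excluded
        )
    df = df.assign(_bin=labels)
    df = df[df["_bin"] >= 0]
    if df.empty:
        raise ValueError(f"block {block!r}: all measurements outside the bin range")

    agg = (
        df.groupby(["subject_id", "feature_id", "_bin"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    subjects = sorted(agg["subject_id"].unique())
    features = sorted(agg["feature_id"].unique())
    tps = bin_spec.labels_desc
    s_idx = {s: i for i, s in enumerate(subjects)}
    f_idx = {f: j for j, f in enumerate(features)}
    t_idx = {t: k for k, t in enumerate(tps)}

    values = np.zeros((len(subjects), len(features), len(tps)))
    mask = np.zeros_like(values, dtype=bool)
    ii = agg["subject_id"].map(s_idx).to_numpy()
    jj = agg["feature_id"].map(f_idx).to_numpy()
    kk = agg["_bin"].map(t_idx).to_numpy()
    values[ii, jj, kk] = agg["value"].to_numpy()
    mask[ii, jj, kk] = True
    return OmicsTensor(values, mask, subjects, features, tps, block)


def _sets_for_block(design: pd.DataFrame, tensor: OmicsTensor) -> list[tuple[str, list[str]]]:
    """Per pair present in the tensor: (case subject, control subjects)."""
    present = set(tensor.subject_ids)
    sets = []
    for pair_id, grp in design.groupby("pair_id", sort=True):
        case = grp.loc[grp["role"] == "case", "subject_id"].tolist()
        ctls = grp.loc[grp["role"] == "control", "subject_id"].tolist()
        case = [s for s in case if s in present]
        ctls = sorted(s for s in ctls if s in present)
        if case or ctls:
            if len(case) != 1:
                raise ValueError(f"pair {pair_id}: expected exactly one case in tensor")
            sets.append((case[0], ctls))
    return sets


def filter_and_split(
    tensor: OmicsTensor,
    design: pd.DataFrame,
    min_observed_timepoints: int = 3,
) -> tuple[OmicsTensor, OmicsTensor]:
    """Split subjects into analysis and validation tensors.

    A subject qualifies for analysis when it has observed data at
    ``min_observed_timepoints`` or more timepoints (a timepoint counts as
    observed when any feature is observed there).  Matched sets are kept
    jointly: if the case or any matched control fails the filter, the whole
    set moves to the validation pool.
    """
    n_obs = dict(zip(tensor.subject_ids, tensor.subject_observed_timepoints()))
    analysis: list[str] = []
    validation: list[str] = []
    for case, ctls in _sets_for_block(design, tensor):
        members = [case] + ctls
        if ctls and all(n_obs[m] >= min_observed_timepoints for m in members):
            analysis.extend(members)
        else:
            validation.extend(members)
    if not analysis:
        raise ValueError("no complete case-control set passes the completeness filter")
    return tensor.subset_subjects(analysis), tensor.subset_subjects(validation)


def within_normalize(tensor: OmicsTensor, design: pd.DataFrame) -> OmicsTensor:
    """Subtract the case-control set mean per feature and timepoint.

    For 1:1 matching the set mean is (case + control)/2.  With several
    controls, the mean control value is computed first and then averaged with
    the case value, so the case carries half the weight regardless of the
    number of controls.  If a member is missing at a timepoint the mean uses
    the available members; if only the case or only controls are observed,
    the observed cells are set missing rather than trivially centered.
    """
    values = tensor.values.copy()
    mask = tensor.mask.copy()
    for case, ctls in _sets_for_block(design, tensor):
        ci = tensor.subject_ids.index(case)
        gi = [tensor.subject_ids.index(c) for c in ctls]
        case_obs = tensor.mask[ci]                       # J x K
        case_val = np.where(case_obs, tensor.values[ci], np.nan)
        if gi:
            ctl_obs = tensor.mask[gi]
            cnt = ctl_obs.sum(axis=0)
            ctl_sum = np.where(ctl_obs, tensor.values[gi], 0.0).sum(axis=0)
            with np.errstate(invalid="ignore"):
                ctl_mean = np.where(cnt > 0, ctl_sum / np.maximum(cnt, 1), np.nan)
        else:
            ctl_mean = np.full(case_obs.shape, np.nan)
        any_ctl = ~np.isnan(ctl_mean)
        both = case_obs & any_ctl
        set_mean = np.where(
            both,
            (case_val + ctl_mean) / 2.0,
            np.where(case_obs, case_val, ctl_mean),
        )
        # cells where only one side of the set is observed become missing
        lonely_case = case_obs & ~any_ctl
        values[ci] = np.where(both, tensor.values[ci] - set_mean, 0.0)
        mask[ci] = case_obs & ~lonely_case
        if lonely_case.any():
            logger.warning(
                "set %s: %d case cells had no observed control and were set missing",
                case, int(lonely_case.sum()),
            )
        for idx in gi:
            usable = tensor.mask[idx] & both
            values[idx] = np.where(usable, tensor.values[idx] - set_mean, 0.0)
            mask[idx] = usable
    out = replace(tensor, values=values, mask=mask)
    out.values[~out.mask] = 0.0
    return out


def write_tensor_bundle(tensor: OmicsTensor, directory: str | Path) -> dict[str, Path]:
    """Write a tensor as long-form values.tsv + mask.tsv + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    I, J, K = tensor.shape
    ii, jj, kk = np.unravel_index(np.arange(I * J * K), (I, J, K))
    long = pd.DataFrame(
        {
            "subject_id": np.asarray(tensor.subject_ids)[ii],
            "feature_id": np.asarray(tensor.feature_ids)[jj],
            "timepoint": np.asarray(tensor.timepoints)[kk],
            "value": tensor.values.ravel(),
            "observed": tensor.mask.ravel().astype(int),
        }
    )
    paths = {
        "values": directory / "values.tsv",
        "sidecar": directory / "tensor.json",
    }
    long.to_csv(paths["values"], sep="\t", index=False, float_format="%.17g")
    paths["sidecar"].write_text(
        json.dumps(
            {
                "block": tensor.block,
                "subjects": tensor.subject_ids,
                "features": tensor.feature_ids,
                "timepoints": tensor.timepoints,
            },
            indent=1,
        )
    )
    return paths


def read_tensor_bundle(directory: str | Path) -> OmicsTensor:
    directory = Path(directory)
    meta = json.loads((directory / "tensor.json").read_text())
    long = pd.read_csv(directory / "values.tsv", sep="\t")
    subjects, features, tps = meta["subjects"], meta["features"], meta["timepoints"]
    s_idx = {s: i for i, s in enumerate(subjects)}
    f_idx = {f: j for j, f in enumerate(features)}
    t_idx = {t: k for k, t in enumerate(tps)}
    values = np.zeros((len(subjects), len(features), len(tps)))
    mask = np.zeros_like(values, dtype=bool)
    ii = long["subject_id"].map(s_idx).to_numpy()
    jj = long["feature_id"].map(f_idx).to_numpy()
    kk = long["timepoint"].map(t_idx).to_numpy()
    values[ii, jj, kk] = long["value"].to_numpy()
    mask[ii, jj, kk] = long["observed"].to_numpy().astype(bool)
    return OmicsTensor(values, mask, subjects, features, tps, meta["block"])
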
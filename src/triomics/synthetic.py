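"""Synthetic longitudinal multi-omics case-control cohort generator.

Emulates a matched case-control design in which each case (a child who
develops islet autoimmunity) is paired with one control for the gene
expression block and three controls for the metabolomics and dietary
biomarker blocks.  Measurements are taken at five visits binned by months
before seroconversion (MBSC: 12, 9, 6, 3, 0), with a planted discriminative
signal concentrated at the early timepoints and block-level
missing-completely-at-random visit dropout.

The generator is the ground-truth source for every downstream stage: it
returns the long-format measurement table, the pairing design table, and a
``SyntheticTruth`` record naming the informative features and their true
per-timepoint effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BlockSpec",
    "CohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "write_fixture",
]

#: default MBSC bin edges, keyed by timepoint label (closed-left/open-right,
#: final bin closed on both ends).
DEFAULT_BIN_EDGES = {
    12: (10.5, 13.5),
    9: (7.5, 10.5),
    6: (4.5, 7.5),
    3: (1.5, 4.5),
    0: (1.0, 1.5),
}

#: default per-timepoint multiplier of the planted effect, ordered by the
#: timepoint labels (descending MBSC).  Larger at 12 and 9 MBSC: the signal
#: is concentrated a year before seroconversion.
DEFAULT_EFFECT_PROFILE = (1.0, 1.0, 0.6, 0.4, 0.4)


@dataclass(frozen=True)
class BlockSpec:
    """One omics block: name, size, and matching ratio (1 or 3 controls/case)."""

    name: str
    n_features: int
    controls_per_case: int = 1

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError(f"block {self.name!r}: n_features must be positive")
        if self.controls_per_case not in (1, 3):
            raise ValueError(
                f"block {self.name!r}: controls_per_case must be 1 or 3, "
                f"got {self.controls_per_case}"
            )


@dataclass
class CohortConfig:
    """Study-design parameters for one synthetic cohort.

    ``effect_size`` is the standardized mean case-control difference at the
    informative features (in units of ``noise_sd``), modulated per timepoint
    by ``effect_time_profile``.
    """

    n_pairs: int = 40
    block_specs: tuple[BlockSpec, ...] = (
        BlockSpec("gene_expression", 200, 1),
        BlockSpec("metabolomics", 100, 3),
        BlockSpec("dietary_biomarkers", 10, 3),
    )
    n_timepoints: int = 5
    timepoint_labels: tuple[int, ...] = (12, 9, 6, 3, 0)
    n_informative_per_block: int = 10
    effect_size: float = 2.0
    effect_time_profile: tuple[float, ...] = DEFAULT_EFFECT_PROFILE
    missing_rate: float = 0.1
    noise_sd: float = 1.0
    seed: int = 0
    #: extra pairs whose subjects are observed at fewer than 3 timepoints;
    #: they end up in the validation split downstream.
    n_validation_pairs: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        if self.n_timepoints != len(self.timepoint_labels):
            raise ValueError("n_timepoints must match timepoint_labels")
        if len(self.effect_time_profile) != self.n_timepoints:
            raise ValueError("effect_time_profile must have one entry per timepoint")
        if not (0.0 <= self.missing_rate < 0.4):
            raise ValueError(
                "missing_rate must lie in [0, 0.4): higher rates make the "
                "at-least-3-of-5-timepoints completeness constraint infeasible"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for spec in self.block_specs:
            if self.n_informative_per_block > spec.n_features:
                raise ValueError(
                    f"n_informative_per_block ({self.n_informative_per_block}) "
                    f"exceeds n_features of block {spec.name!r}"
                )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    informative_features: dict[str, list[str]]
    #: per block: feature_id -> list of per-timepoint additive effects
    effects: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    #: subject_id -> "case" | "control"
    labels: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "informative_features": self.informative_features,
                "effects": self.effects,
                "labels": self.labels,
            },
            indent=1,
            sort_keys=True,
        )


def _subject_ids(pair: int, n_controls: int) -> tuple[str, list[str]]:
    case = f"P{pair:03d}_case"
    controls = [f"P{pair:03d}_ctl{c + 1}" for c in range(n_controls)]
    return case, controls


def _sample_observed_mask(
    rng: np.random.Generator, n_tp: int, missing_rate: float, min_observed: int
) -> np.ndarray:
    """Bernoulli visit dropout, repaired so >= min_observed visits remain."""
    miss = rng.random(n_tp) < missing_rate
    n_obs = n_tp - miss.sum()
    while n_obs < min_observed:
        # restore a uniformly chosen missing visit
        missing_idx = np.flatnonzero(miss)
        miss[rng.choice(missing_idx)] = False
        n_obs += 1
    return ~miss


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate long-format measurements, the pairing design, and ground truth.

    The value model is ``x = subject_intercept + noise + planted_effect``:
    i.i.d. Gaussian(0, noise_sd) noise per subject x feature x timepoint, a
    subject-level random intercept (SD = 0.5 x noise_sd, constant over time)
    to make within-pair normalization non-trivial, and for cases only an
    additive shift ``effect_size * profile[t] * noise_sd`` at informative
    features.  Missingness removes entire subject x timepoint x block visit
    vectors (MCAR), never single cells, and is repaired so that every
    analysis subject keeps at least 3 observed timepoints.

    Identical ``config`` (including seed) yields identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n_ctrl_max = max(s.controls_per_case for s in config.block_specs)
    tp_labels = list(config.timepoint_labels)
    n_tp = config.n_timepoints

    truth = SyntheticTruth(informative_features={})
    meas_rows: list[pd.DataFrame] = []
    design_rows: list[dict] = []

    total_pairs = config.n_pairs + config.n_validation_pairs
    sexes = rng.choice(["F", "M"], size=total_pairs)
    countries = rng.choice(["FIN", "SWE", "GER", "USA"], size=total_pairs)

    # MBSC sampling times: jitter uniformly inside each bin's boundaries
    edges = [DEFAULT_BIN_EDGES[t] for t in tp_labels]

    for spec in config.block_specs:
        feat_ids = [f"{spec.name[:3]}_{j:04d}" for j in range(spec.n_features)]
        informative = sorted(
            rng.choice(spec.n_features, size=config.n_informative_per_block, replace=False)
        )
        truth.informative_features[spec.name] = [feat_ids[j] for j in informative]
        effect = np.zeros((spec.n_features, n_tp))
        profile = np.asarray(config.effect_time_profile, dtype=float)
        effect[informative, :] = config.effect_size * config.noise_sd * profile
        truth.effects[spec.name] = {
            feat_ids[j]: [float(v) for v in effect[j]] for j in informative
        }

        for pair in range(total_pairs):
            is_validation = pair >= config.n_pairs
            case_id, all_ctls = _subject_ids(pair, n_ctrl_max)
            ctl_ids = all_ctls[: spec.controls_per_case]
            for subject, role in [(case_id, "case")] + [(c, "control") for c in ctl_ids]:
                truth.labels[subject] = role
                intercept = rng.normal(0.0, 0.5 * config.noise_sd, size=spec.n_features)
                values = intercept[:, None] + rng.normal(
                    0.0, config.noise_sd, size=(spec.n_features, n_tp)
                )
                if role == "case":
                    values = values + effect
                if is_validation:
                    # deliberately sparse: 1 or 2 observed visits
                    n_obs = int(rng.integers(1, 3))
                    observed = np.zeros(n_tp, dtype=bool)
                    observed[rng.choice(n_tp, size=n_obs, replace=False)] = True
                else:
                    observed = _sample_observed_mask(
                        rng, n_tp, config.missing_rate, min_observed=3
                    )
                mbsc = np.array(
                    [lo + (hi - lo) * rng.random() for lo, hi in edges]
                )
                obs_k = np.flatnonzero(observed)
                n_rows = obs_k.size * spec.n_features
                meas_rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": np.repeat(subject, n_rows),
                            "pair_id": np.repeat(f"P{pair:03d}", n_rows),
                            "role": np.repeat(role, n_rows),
                            "block": np.repeat(spec.name, n_rows),
                            "feature_id": np.tile(feat_ids, obs_k.size),
                            "months_before_sc": np.repeat(mbsc[obs_k], spec.n_features),
                            "value": values[:, obs_k].T.ravel(),
                        }
                    )
                )

    for pair in range(total_pairs):
        case_id, all_ctls = _subject_ids(pair, n_ctrl_max)
        design_rows.append(
            {
                "pair_id": f"P{pair:03d}",
                "subject_id": case_id,
                "role": "case",
                "blocks": ";".join(s.name for s in config.block_specs),
                "sex": sexes[pair],
                "country": countries[pair],
            }
        )
        for idx, ctl in enumerate(all_ctls):
            blocks = [s.name for s in config.block_specs if idx < s.controls_per_case]
            if not blocks:
                continue
            design_rows.append(
                {
                    "pair_id": f"P{pair:03d}",
                    "subject_id": ctl,
                    "role": "control",
                    "blocks": ";".join(blocks),
                    "sex": sexes[pair],
                    "country": countries[pair],
                }
            )

    measurements = pd.concat(meas_rows, ignore_index=True)
    design = pd.DataFrame(design_rows)
    return measurements, design, truth


def write_fixture(
    measurements: pd.DataFrame,
    design: pd.DataFrame,
    truth: SyntheticTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write measurements.tsv, design.tsv and truth.json under ``directory``.

    Numeric values are written with enough digits to round-trip through the
    tensor-building reader losslessly.  An empty measurement table raises
    before any file is created.
    """
    if measurements.empty:
        raise ValueError("measurement table is empty; nothing to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": directory / "measurements.tsv",
        "design": directory / "design.tsv",
        "truth": directory / "truth.json",
    }
    measurements.to_csv(paths["measurements"], sep="\t", index=False, float_format="%.17g")
    design.to_csv(paths["design"], sep="\t", index=False)
    paths["truth"].write_text(truth.to_json())
    return paths
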
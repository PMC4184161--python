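"""Synthetic expression datasets with donor-level haplotype structure.

The generator emulates the statistical world the scoring method assumes:

* *haplotype marker probes*: each donor is in a "high" state with
  probability ``minor_allele_freq``; every sample of the donor then draws
  its log2 intensity around ``mode_high_log2``, otherwise around
  ``mode_low_log2`` (equal spread ``sd_log2`` per mode).  States are
  constant within a donor, so multiple samples per donor share the score.
* *gender probes*: four Y-linked-like probes high in males plus one
  XIST-like probe high in females, named after the usual gender-QC probe
  sets so the default gender panel applies directly.
* *background probes*: unimodal noise centred midway between the modes.
* *mix-ups*: a configurable fraction of samples has its recorded donor id
  (and with it the declared sex) reassigned to a different donor, with the
  truth kept for evaluation.

Defaults give 12 donors x 4 samples (48 arrays, the training-set scale),
three marker probes named after the default HLA panel with modes at log2 4
and 10 (linear 16 and 1024, valley at the panel threshold 128 = 2^7), and a
minor-state frequency of 0.3, which lands planted dips in the 0.12-0.15
range typical of real fingerprinting probe sets.  Intensities are exported
on the linear scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hlascore.scoring import DEFAULT_GENDER_PANEL, DEFAULT_HLA_PANEL

_HLA_PROBE_IDS = [p for p, _ in DEFAULT_HLA_PANEL.probes]
_GENDER_MALE_IDS = [p for p, _ in DEFAULT_GENDER_PANEL.male_probes]
_GENDER_FEMALE_IDS = [p for p, _ in DEFAULT_GENDER_PANEL.female_probes]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic dataset; defaults are the stated
    world described in the module docstring."""

    n_donors: int = 12
    samples_per_donor: int = 4
    n_probes_total: int = 100
    n_bimodal: int = 3
    minor_allele_freq: float = 0.3
    mode_low_log2: float = 4.0
    mode_high_log2: float = 10.0
    sd_log2: float = 0.5
    n_gender_probes: int = 5
    frac_female: float = 0.5
    mixup_rate: float = 0.0
    seed: int = 0
    dataset_id: str = "SIM1"

    def validate(self) -> None:
        problems = []
        if self.n_donors < 1:
            problems.append("n_donors must be >= 1")
        if self.samples_per_donor < 1:
            problems.append("samples_per_donor must be >= 1")
        if self.n_bimodal < 0 or self.n_gender_probes < 0:
            problems.append("probe counts must be non-negative")
        if self.n_bimodal + self.n_gender_probes > self.n_probes_total:
            problems.append("n_bimodal + n_gender_probes must not exceed n_probes_total")
        if not 0.0 < self.minor_allele_freq <= 0.5:
            problems.append("minor_allele_freq must lie in (0, 0.5]")
        if self.mode_high_log2 <= self.mode_low_log2:
            problems.append("mode_high_log2 must exceed mode_low_log2")
        if self.sd_log2 <= 0:
            problems.append("sd_log2 must be positive")
        if self.n_gender_probes not in (0, 5):
            problems.append("n_gender_probes must be 0 or 5 (the gender-QC panel size)")
        if not 0.0 <= self.frac_female <= 1.0:
            problems.append("frac_female must lie in [0, 1]")
        if not 0.0 <= self.mixup_rate < 1.0:
            problems.append("mixup_rate must lie in [0, 1)")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated dataset.

    ``donor_states``: bimodal probes x donors, True where the donor is in
    the high mode.  ``donor_sex``: donor id -> 'F'/'M'.  ``sample_donor``:
    sample id -> true donor.  ``swaps``: injected mislabels.
    """

    donor_states: pd.DataFrame = field(repr=False)
    donor_sex: pd.Series = field(repr=False)
    sample_donor: pd.Series = field(repr=False)
    swaps: pd.DataFrame = field(repr=False)

    def true_score(self, donor_id: str, probe_ids) -> str:
        """Noise-free score of a donor over the given marker probes."""
        return "".join(
            "1" if self.donor_states.loc[p, donor_id] else "0" for p in probe_ids
        )


def _probe_names(config: SimConfig) -> tuple[list[str], list[str], list[str]]:
    if config.n_bimodal <= len(_HLA_PROBE_IDS):
        bimodal = _HLA_PROBE_IDS[: config.n_bimodal]
    else:
        bimodal = _HLA_PROBE_IDS + [
            f"bimodal_{i:04d}_at" for i in range(config.n_bimodal - len(_HLA_PROBE_IDS))
        ]
    gender = (_GENDER_MALE_IDS + _GENDER_FEMALE_IDS) if config.n_gender_probes == 5 else []
    n_bg = config.n_probes_total - config.n_bimodal - config.n_gender_probes
    background = [f"background_{i:04d}_at" for i in range(n_bg)]
    return bimodal, gender, background


def generate_dataset(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate (matrix, annotation, truth) for one dataset.

    The matrix is probes x samples on the linear scale; the annotation has
    columns sample_id, donor_id, timepoint, declared_sex, dataset_id (donor
    ids possibly falsified when ``mixup_rate > 0``); everything is
    reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    donors = [f"D{i:03d}" for i in range(config.n_donors)]
    sample_ids = [
        f"S{i:03d}_T{t + 1}"
        for i in range(config.n_donors)
        for t in range(config.samples_per_donor)
    ]
    sample_donor = pd.Series(
        [d for d in donors for _ in range(config.samples_per_donor)],
        index=sample_ids,
        name="true_donor_id",
    )
    donor_sex = pd.Series(
        np.where(rng.random(config.n_donors) < config.frac_female, "F", "M"),
        index=donors,
        name="sex",
    )

    bimodal, gender, background = _probe_names(config)
    n_samples = len(sample_ids)
    blocks = []

    states = pd.DataFrame(
        rng.random((len(bimodal), config.n_donors)) < config.minor_allele_freq,
        index=bimodal,
        columns=donors,
    )
    if bimodal:
        per_sample_state = states.loc[:, sample_donor.to_numpy()].to_numpy()
        means = np.where(per_sample_state, config.mode_high_log2, config.mode_low_log2)
        blocks.append(means + rng.normal(0.0, config.sd_log2, means.shape))
    if gender:
        is_male = (donor_sex.loc[sample_donor.to_numpy()] == "M").to_numpy()
        rows = []
        for p in gender:
            high_for_male = p in _GENDER_MALE_IDS
            high = is_male if high_for_male else ~is_male
            rows.append(np.where(high, config.mode_high_log2, config.mode_low_log2))
        blocks.append(np.array(rows) + rng.normal(0.0, config.sd_log2, (len(gender), n_samples)))
    if background:
        mid = 0.5 * (config.mode_low_log2 + config.mode_high_log2)
        blocks.append(rng.normal(mid, config.sd_log2, (len(background), n_samples)))

    log2_matrix = np.vstack(blocks) if blocks else np.empty((0, n_samples))
    matrix = pd.DataFrame(
        np.exp2(log2_matrix), index=bimodal + gender + background, columns=sample_ids
    )
    matrix.index.name = "probe_id"

    annotation = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": sample_donor.to_numpy(),
            "timepoint": [t + 1 for _ in range(config.n_donors) for t in range(config.samples_per_donor)],
            "declared_sex": donor_sex.loc[sample_donor.to_numpy()].to_numpy(),
            "dataset_id": config.dataset_id,
        }
    )
    annotation, swaps = inject_mixups(
        annotation, config.mixup_rate, seed=rng.integers(2**31), donor_sex=donor_sex
    )
    truth = SimTruth(
        donor_states=states, donor_sex=donor_sex, sample_donor=sample_donor, swaps=swaps
    )
    return matrix, annotation, truth


def inject_mixups(
    annotation: pd.DataFrame,
    rate: float,
    seed: int,
    donor_sex: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reassign the recorded donor of ``ceil(rate * n)`` random samples.

    Swaps are donor-label reassignments (intensities stay with the sample),
    so the returned swap table is exact ground truth.  The declared sex
    follows the recorded donor when ``donor_sex`` is given, mimicking an
    annotation database keyed by donor.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("mixup rate must lie in [0, 1)")
    out = annotation.copy().reset_index(drop=True)
    n = len(out)
    n_swaps = math.ceil(rate * n)
    if n_swaps == 0:
        return out, pd.DataFrame(columns=["sample_id", "true_donor_id", "recorded_donor_id"])
    donors = list(pd.unique(out["donor_id"]))
    if len(donors) < 2:
        raise ValueError("mix-up injection needs at least two donors")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_swaps, replace=False)
    records = []
    for i in chosen:
        true_donor = out.at[i, "donor_id"]
        others = [d for d in donors if d != true_donor]
        new_donor = others[rng.integers(len(others))]
        out.at[i, "donor_id"] = new_donor
        if donor_sex is not None:
            out.at[i, "declared_sex"] = donor_sex[new_donor]
        records.append((out.at[i, "sample_id"], true_donor, new_donor))
    swaps = pd.DataFrame(records, columns=["sample_id", "true_donor_id", "recorded_donor_id"])
    return out, swaps
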
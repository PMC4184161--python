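"""Binary panel scoring, gender calling and donor-consistency flagging.

The HLA-score reduces a sample to an ordered string of binary digits, one
per marker probe set: 1 when the measured linear intensity surpasses
(strictly exceeds) that probe set's threshold, 0 otherwise.  Samples from
the same donor must share the score, because the underlying haplotype does
not change between time points; a score difference within a donor points to
an annotation problem.

Two severities are distinguished when a sample disagrees with its donor's
reference (majority) score:

* SOFT - every discordant digit comes from an intensity within
  ``soft_band_log2`` (default 1.0, i.e. two-fold) of the threshold: a slight
  transgression, not critical;
* HARD - at least one discordant intensity is far from the threshold:
  possible sample mix-up, follow up.

A gender panel (Y-linked transcripts high in males, XIST high in females)
supplies an orthogonal check; a call that contradicts the declared sex, or
gender calls that disagree within a donor, escalate the flag to HARD.

The default three-probe HLA panel is 203290_at (HLA-DQA1*0401-specific),
213831_at (HLA-DQA1*0103-specific) and 209728_at (HLA-DRB4), each with a
linear threshold of 128 (log2 scale 7).  Thresholds are per-probe and
should be re-tuned per tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

FLAG_OK = "OK"
FLAG_SOFT = "SOFT"
FLAG_HARD = "HARD"
_FLAG_ORDER = {FLAG_OK: 0, FLAG_SOFT: 1, FLAG_HARD: 2}

REPORT_COLUMNS = [
    "sample_id",
    "donor_id",
    "hla_score",
    "reference_score",
    "flag",
    "reasons",
    "note",
]


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker probe sets with per-probe linear thresholds.

    The probe order defines the digit positions of the score.
    """

    name: str
    probes: tuple[tuple[str, float], ...]

    def __post_init__(self):
        ids = [p for p, _ in self.probes]
        if len(set(ids)) != len(ids):
            raise ValueError("panel probe ids must be unique")
        if any(t <= 0 for _, t in self.probes):
            raise ValueError("panel thresholds must be positive")

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.probes)

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.probes)

    def __len__(self) -> int:
        return len(self.probes)

    def n_possible_scores(self) -> int:
        return 2 ** len(self.probes)

    def possible_scores(self) -> list[str]:
        return [format(i, f"0{len(self.probes)}b") for i in range(2 ** len(self.probes))]


DEFAULT_HLA_PANEL = MarkerPanel(
    "HLA-score",
    (("203290_at", 128.0), ("213831_at", 128.0), ("209728_at", 128.0)),
)


@dataclass(frozen=True)
class GenderPanel:
    """Gender-QC panel: Y-linked probes (high in males) plus XIST-like
    probes (high in females), with configurable linear thresholds."""

    name: str
    male_probes: tuple[tuple[str, float], ...]
    female_probes: tuple[tuple[str, float], ...]

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.male_probes + self.female_probes)


# RPS4Y1 / EIF1AY / DDX3Y / KDM5D / XIST probe sets; the 128 thresholds are
# working defaults, not published calibrations -- override per dataset.
DEFAULT_GENDER_PANEL = GenderPanel(
    "REDKX",
    male_probes=(
        ("201909_at", 128.0),
        ("204409_s_at", 128.0),
        ("205000_at", 128.0),
        ("206700_s_at", 128.0),
    ),
    female_probes=(("224588_at", 128.0),),
)


@dataclass(frozen=True)
class SampleScore:
    """Binary digit string of one sample under one panel."""

    sample_id: str
    digits: str
    intensities: tuple[float, ...]


def score_sample(intensities, panel: MarkerPanel, sample_id: str = "") -> SampleScore:
    """Score one sample: digit i is 1 iff intensity i strictly exceeds
    threshold i, in panel order."""
    vals = np.asarray(intensities, dtype=float).ravel()
    if vals.size != len(panel):
        raise ValueError(
            f"expected {len(panel)} intensities for panel {panel.name!r}, got {vals.size}"
        )
    if not np.all(np.isfinite(vals)) or np.any(vals < 0):
        raise ValueError("intensities must be finite and non-negative")
    digits = "".join(
        "1" if v > t else "0" for v, t in zip(vals, panel.thresholds)
    )
    return SampleScore(sample_id=sample_id, digits=digits, intensities=tuple(vals))


def score_samples(matrix: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Score every sample of a probes x samples matrix.

    Returns a DataFrame indexed by sample id with one column per panel probe
    (the linear intensity) plus a ``score`` column.
    """
    missing = [p for p in panel.probe_ids if p not in matrix.index]
    if missing:
        raise KeyError(f"panel probe sets missing from matrix: {', '.join(missing)}")
    sub = matrix.loc[list(panel.probe_ids)].T  # samples x probes
    scores = [
        score_sample(row, panel, sample_id=str(s)).digits
        for s, row in zip(sub.index, sub.to_numpy(dtype=float))
    ]
    out = sub.copy()
    out["score"] = scores
    return out


@dataclass(frozen=True)
class GenderCall:
    sample_id: str
    call: str  # 'F', 'M' or 'ambiguous'
    evidence: dict = field(repr=False)


def call_gender(intensities, gender_panel: GenderPanel = DEFAULT_GENDER_PANEL,
                sample_id: str = "") -> GenderCall:
    """Unanimous-panel gender call.

    ``intensities`` maps probe id to linear intensity.  M requires every
    Y-linked probe above its threshold and every female probe below; F the
    reverse; anything else is ambiguous.
    """
    evidence = {}
    for probe, thr in gender_panel.male_probes + gender_panel.female_probes:
        if probe not in intensities:
            raise KeyError(f"gender-panel probe {probe!r} missing")
        evidence[probe] = 1 if float(intensities[probe]) > thr else 0
    male_high = all(evidence[p] for p, _ in gender_panel.male_probes)
    male_low = not any(evidence[p] for p, _ in gender_panel.male_probes)
    female_high = all(evidence[p] for p, _ in gender_panel.female_probes)
    female_low = not any(evidence[p] for p, _ in gender_panel.female_probes)
    if male_high and female_low:
        call = "M"
    elif male_low and female_high:
        call = "F"
    else:
        call = "ambiguous"
    return GenderCall(sample_id=sample_id, call=call, evidence=evidence)


def call_genders(matrix: pd.DataFrame, gender_panel: GenderPanel = DEFAULT_GENDER_PANEL
                 ) -> pd.Series:
    """Gender call per sample of a probes x samples matrix."""
    calls = {}
    for s in matrix.columns:
        calls[s] = call_gender(matrix[s].to_dict(), gender_panel, sample_id=str(s)).call
    return pd.Series(calls, name="gender_call")


def _majority_reference(scores: list[str]) -> str:
    """Majority score; ties resolved by the earliest sample's score."""
    counts: dict[str, int] = {}
    for s in scores:
        counts[s] = counts.get(s, 0) + 1
    best = max(counts.values())
    for s in scores:  # first score reaching the top count wins ties
        if counts[s] == best:
            return s
    raise AssertionError("unreachable")


def check_donor_consistency(
    scored: pd.DataFrame,
    annotation: pd.DataFrame,
    panel: MarkerPanel = DEFAULT_HLA_PANEL,
    soft_band_log2: float = 1.0,
) -> pd.DataFrame:
    """Flag samples whose score disagrees with their donor's reference.

    Parameters
    ----------
    scored : output of :func:`score_samples` (per-probe intensities plus a
        ``score`` column, indexed by sample id).
    annotation : table with ``sample_id`` and ``donor_id`` columns; its row
        order defines the tie-break for the reference score.
    soft_band_log2 : half-width (log2 scale) of the band around a threshold
        within which a discordant digit is only SOFT.

    Returns one row per annotated sample with flag OK/SOFT/HARD and
    human-readable reasons; a donor with a single sample is OK with note
    ``no repeat``.
    """
    ann = annotation.reset_index(drop=True)
    missing = [s for s in ann["sample_id"] if s not in scored.index]
    if missing:
        raise KeyError(f"samples absent from score table: {', '.join(map(str, missing))}")
    rows = []
    for donor, grp in ann.groupby("donor_id", sort=False):
        samples = list(grp["sample_id"])
        scores = [scored.loc[s, "score"] for s in samples]
        if len(samples) == 1:
            rows.append((samples[0], donor, scores[0], scores[0], FLAG_OK, [], "no repeat"))
            continue
        ref = _majority_reference(scores)
        for s, sc in zip(samples, scores):
            if sc == ref:
                rows.append((s, donor, sc, ref, FLAG_OK, [], ""))
                continue
            reasons = []
            all_soft = True
            for pos, (probe, thr) in enumerate(panel.probes):
                if sc[pos] == ref[pos]:
                    continue
                v = float(scored.loc[s, probe])
                dist = abs(np.log2(max(v, 1e-12) / thr))
                fold = max(v, 1e-12) / thr
                fold = fold if fold >= 1 else 1 / fold
                within = dist <= soft_band_log2
                all_soft &= within
                side = "above" if v > thr else "below"
                reasons.append(
                    f"{probe} intensity {v:g} {side} threshold {thr:g} "
                    f"({fold:.1f}-fold), donor reference digit {ref[pos]}"
                )
            flag = FLAG_SOFT if all_soft else FLAG_HARD
            rows.append((s, donor, sc, ref, flag, reasons, ""))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def combine_with_gender(
    report: pd.DataFrame,
    gender_calls,
    declared_sex,
) -> pd.DataFrame:
    """Escalate flags with gender evidence.

    Adds a HARD ``gender mismatch`` reason when a sample's call (F/M)
    contradicts its declared sex, or when non-ambiguous calls disagree
    within a donor (the minority against the donor's majority call).  Flags
    only ever escalate (OK < SOFT < HARD).
    """
    calls = pd.Series(gender_calls)
    declared = pd.Series(declared_sex)
    out = report.copy()
    out["gender_call"] = [calls.get(s, "ambiguous") for s in out["sample_id"]]
    out["declared_sex"] = [declared.get(s, "") for s in out["sample_id"]]

    # donor-majority call over non-ambiguous samples, ties to the first
    donor_majority = {}
    for donor, grp in out.groupby("donor_id", sort=False):
        proper = [c for c in grp["gender_call"] if c in ("F", "M")]
        donor_majority[donor] = _majority_reference(proper) if proper else None

    new_flags, new_reasons = [], []
    for _, row in out.iterrows():
        flag, reasons = row["flag"], list(row["reasons"])
        call, decl = row["gender_call"], row["declared_sex"]
        if call in ("F", "M") and decl in ("F", "M") and call != decl:
            reasons.append(f"gender mismatch: called {call}, declared {decl}")
            flag = FLAG_HARD
        maj = donor_majority[row["donor_id"]]
        if call in ("F", "M") and maj in ("F", "M") and call != maj:
            reasons.append(f"gender differs within donor (called {call}, donor majority {maj})")
            flag = FLAG_HARD
        # escalation only
        if _FLAG_ORDER[flag] < _FLAG_ORDER[row["flag"]]:
            flag = row["flag"]
        new_flags.append(flag)
        new_reasons.append(reasons)
    out["flag"] = new_flags
    out["reasons"] = new_reasons
    return out


def summarize_dataset(
    report: pd.DataFrame,
    annotation: pd.DataFrame,
    soft_counts_as_flagged: bool = False,
) -> pd.DataFrame:
    """Per-dataset summary of the flag report.

    ``n_flagged`` counts HARD flags (SOFT is "not critical" by default);
    ``n_gender_fail`` counts samples with a gender reason; ``n_score_diff``
    counts samples whose score differs from the donor reference (SOFT or
    HARD).
    """
    ann = annotation.set_index("sample_id")
    rep = report.set_index("sample_id")
    rep["dataset_id"] = ann.loc[rep.index, "dataset_id"]
    tissue_col = "tissue" if "tissue" in ann.columns else None
    flag_levels = (
        (FLAG_HARD, FLAG_SOFT) if soft_counts_as_flagged else (FLAG_HARD,)
    )
    rows = []
    for ds, grp in rep.groupby("dataset_id", sort=False):
        donors = ann.loc[grp.index].groupby("donor_id").size()
        gender_fail = sum(
            any("gender" in r for r in reasons) for reasons in grp["reasons"]
        )
        rows.append(
            {
                "dataset_id": ds,
                "tissue": ann.loc[grp.index, tissue_col].iloc[0] if tissue_col else "",
                "n_samples": len(grp),
                "n_donors_with_repeats": int((donors > 1).sum()),
                "n_flagged": int(grp["flag"].isin(flag_levels).sum()),
                "n_gender_fail": int(gender_fail),
                "n_score_diff": int((grp["hla_score"] != grp["reference_score"]).sum()),
            }
        )
    return pd.DataFrame(rows)


def load_allele_matrix() -> pd.DataFrame:
    """Packaged allele x probe match matrix for the two HLA-DQA1 probe sets.

    1 marks a probe whose sequence matches the allele's transcript exactly;
    the matrix ships as static reference data (the underlying sequence
    alignment is not recomputed here).
    """
    with resources.files("hlascore.data").joinpath(
        "hla_dqa1_allele_probe_matches.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def compatible_alleles(
    dqa1_digits,
    match_floor: int = 9,
    allele_matrix: pd.DataFrame | None = None,
) -> list[str]:
    """HLA-DQA1 alleles compatible with the two DQA1 digits of a score.

    ``dqa1_digits`` holds the digits for 203290_at and 213831_at.  A digit
    of 1 restricts to alleles matching at least ``match_floor`` of the 11
    probes of that probe set; 0 restricts to the complement.  Returns the
    (possibly empty, then unresolved) intersection.
    """
    digits = [int(d) for d in dqa1_digits]
    if len(digits) != 2 or any(d not in (0, 1) for d in digits):
        raise ValueError("expected two binary digits (203290_at, 213831_at)")
    am = load_allele_matrix() if allele_matrix is None else allele_matrix
    probe_cols = [f"p{i}" for i in range(1, 12)]
    compatible = None
    for probe_set, digit in zip(("203290_at", "213831_at"), digits):
        sub = am[am["probe_set"] == probe_set]
        counts = sub[probe_cols].sum(axis=1)
        high = set(sub.loc[counts >= match_floor, "allele"])
        group = high if digit == 1 else set(sub["allele"]) - high
        compatible = group if compatible is None else compatible & group
    return sorted(compatible)
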
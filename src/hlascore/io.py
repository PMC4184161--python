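"""Readers and writers for expression matrices, annotations and reports.

Matrices travel as TSV/CSV (first column probe id, header row of sample
ids) or GCT 1.2; annotations as TSV with the columns sample_id, donor_id,
timepoint, declared_sex, dataset_id.  Panel definitions come from a YAML
config.  A small example dataset (marker intensities for 20 serial samples
from five donors of a public PBMC study) ships with the package.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from hlascore.scoring import GenderPanel, MarkerPanel

ANNOTATION_COLUMNS = ["sample_id", "donor_id", "timepoint", "declared_sex", "dataset_id"]


class InputError(ValueError):
    """Malformed or unreadable user input."""


def read_matrix(path) -> pd.DataFrame:
    """Read a probes x samples intensity matrix (TSV, CSV or GCT 1.2)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"matrix file not found: {path}")
    try:
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
        if first.startswith("#1.2"):
            df = pd.read_csv(path, sep="\t", skiprows=2)
            df = df.drop(columns=["Description"], errors="ignore")
            df = df.set_index(df.columns[0])
        else:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
            df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise InputError(f"cannot parse matrix file {path}: {e}") from e
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise InputError(f"matrix file {path} contains no data")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise InputError(f"matrix file {path} has duplicate probe or sample ids")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise InputError(f"matrix file {path} has non-numeric entries: {e}") from e
    if df.isna().any().any():
        raise InputError(f"matrix file {path} has missing entries")
    df.index.name = "probe_id"
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a matrix in the layout implied by the extension (.gct for GCT
    1.2, .csv for comma-separated, anything else tab-separated)."""
    path = Path(path)
    if path.suffix.lower() == ".gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            out = matrix.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t")
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        out = matrix.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep=sep)


def read_annotation(path) -> pd.DataFrame:
    """Read a sample-annotation TSV and check the required columns."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    try:
        ann = pd.read_csv(path, sep="\t", dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise InputError(f"cannot parse annotation file {path}: {e}") from e
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise InputError(
            f"annotation file {path} lacks required columns: {', '.join(missing)}"
        )
    if ann["sample_id"].duplicated().any():
        raise InputError(f"annotation file {path} has duplicate sample ids")
    return ann


def read_panel_config(path) -> dict:
    """Read a YAML panel/run configuration.

    Recognised keys: ``panel`` (name, probes: list of {probe_id,
    threshold}), ``gender_panel`` (name, male_probes, female_probes, same
    shape) and free-form scalar options passed through.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    except yaml.YAMLError as e:
        raise InputError(f"cannot parse config file {path}: {e}") from e
    out = dict(cfg)
    if "panel" in cfg:
        p = cfg["panel"]
        try:
            out["panel"] = MarkerPanel(
                p.get("name", "custom"),
                tuple((str(e["probe_id"]), float(e["threshold"])) for e in p["probes"]),
            )
        except (KeyError, TypeError, ValueError) as e:
            raise InputError(f"malformed panel definition in {path}: {e}") from e
    if "gender_panel" in cfg:
        p = cfg["gender_panel"]
        try:
            out["gender_panel"] = GenderPanel(
                p.get("name", "gender"),
                male_probes=tuple(
                    (str(e["probe_id"]), float(e["threshold"])) for e in p["male_probes"]
                ),
                female_probes=tuple(
                    (str(e["probe_id"]), float(e["threshold"])) for e in p["female_probes"]
                ),
            )
        except (KeyError, TypeError, ValueError) as e:
            raise InputError(f"malformed gender panel definition in {path}: {e}") from e
    return out


def write_report(report: pd.DataFrame, path) -> None:
    """Write a flag report as TSV, joining reason lists for readability."""
    out = report.copy()
    if "reasons" in out.columns:
        out["reasons"] = ["; ".join(r) for r in out["reasons"]]
    out.to_csv(path, sep="\t", index=False)


def load_example_matrix() -> pd.DataFrame:
    """Packaged marker intensities of the 20-sample example dataset."""
    with resources.files("hlascore.data").joinpath("example_marker_intensities.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index.name = "probe_id"
    return df.astype(float)


def load_example_annotation() -> pd.DataFrame:
    """Annotation of the example dataset, including the published gender-QC
    call in the ``redkx_call`` column."""
    with resources.files("hlascore.data").joinpath("example_annotation.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)
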
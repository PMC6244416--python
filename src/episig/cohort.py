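"""The in-memory methylation cohort: beta matrix + sample sheet + probe manifest.

Every pipeline stage consumes and returns a :class:`MethylationCohort`.  Betas
are stored probe × sample (probes in rows, as in the TSV interchange format),
the sample sheet is indexed by sample id, and the manifest by probe id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["chrom", "pos", "gene", "island_relation",
                    "sex_chromosome", "snp_overlap", "cross_reactive"]
SAMPLE_COLUMNS = ["group", "age", "sex", "batch", "array_type"]


@dataclass
class MethylationCohort:
    """Beta-value matrix with its sample sheet and probe manifest.

    Parameters
    ----------
    betas : probe × sample DataFrame of methylation fractions in [0, 1].
    samples : sample sheet indexed by sample id with columns
        ``group, age, sex, batch, array_type``.
    manifest : probe annotation indexed by probe id with columns
        ``chrom, pos, gene, island_relation, sex_chromosome, snp_overlap,
        cross_reactive``.
    detection_p : optional probe × sample detection p-value matrix.
    """

    betas: pd.DataFrame
    samples: pd.DataFrame
    manifest: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.betas.columns.duplicated().any():
            raise ValueError("duplicate sample ids in beta matrix")
        if not self.betas.columns.equals(pd.Index(self.samples.index)):
            # allow arbitrary order in the sheet, but the sets must match
            if set(self.betas.columns) != set(self.samples.index):
                raise ValueError("beta matrix columns do not match sample sheet")
            self.samples = self.samples.loc[self.betas.columns]
        if not np.isfinite(self.betas.to_numpy()).all():
            raise ValueError("beta matrix contains non-finite values")

    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    def subset_probes(self, probe_ids) -> "MethylationCohort":
        probe_ids = pd.Index(probe_ids)
        return replace(
            self,
            betas=self.betas.loc[probe_ids],
            manifest=self.manifest.loc[self.manifest.index.intersection(probe_ids)],
            detection_p=None if self.detection_p is None else self.detection_p.loc[probe_ids],
        )

    def subset_samples(self, sample_ids) -> "MethylationCohort":
        sample_ids = list(sample_ids)
        return replace(
            self,
            betas=self.betas[sample_ids],
            samples=self.samples.loc[sample_ids],
            detection_p=None if self.detection_p is None else self.detection_p[sample_ids],
        )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort, for validation only.

    ``planted_probe_ids`` maps block label → probe ids; ``planted_effects``
    maps probe id → {group label: signed Δβ}; ``planted_regions`` is a list of
    ``(chrom, start, end, probe_ids)`` tuples (1-based inclusive positions);
    ``true_cell_proportions`` is a sample × cell-type DataFrame;
    ``true_subtype`` maps sample id → group label.
    """

    planted_probe_ids: dict[str, list[str]] = field(default_factory=dict)
    planted_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_regions: list[tuple] = field(default_factory=list)
    true_cell_proportions: pd.DataFrame | None = None
    true_subtype: dict[str, str] = field(default_factory=dict)

    def all_planted_probes(self) -> set[str]:
        out: set[str] = set()
        for ids in self.planted_probe_ids.values():
            out.update(ids)
        return out

    def to_json(self) -> str:
        props = self.true_cell_proportions
        return json.dumps({
            "planted_probe_ids": self.planted_probe_ids,
            "planted_effects": self.planted_effects,
            "planted_regions": [list(r[:3]) + [list(r[3])] for r in self.planted_regions],
            "true_cell_proportions": None if props is None else {
                "index": list(props.index), "columns": list(props.columns),
                "values": props.to_numpy().tolist()},
            "true_subtype": self.true_subtype,
        })

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        props = d["true_cell_proportions"]
        if props is not None:
            props = pd.DataFrame(props["values"], index=props["index"],
                                 columns=props["columns"])
        return cls(
            planted_probe_ids=d["planted_probe_ids"],
            planted_effects=d["planted_effects"],
            planted_regions=[(r[0], r[1], r[2], list(r[3])) for r in d["planted_regions"]],
            true_cell_proportions=props,
            true_subtype=d["true_subtype"],
        )


def export_fixture(cohort: MethylationCohort, truth: GroundTruth | None,
                   directory: str | Path) -> dict[str, Path]:
    """Write a cohort (and optionally its ground truth) as plain-text files.

    Produces ``betas.tsv`` (first column probe_id), ``samples.csv``,
    ``manifest.tsv`` and, when truth is given, ``truth.json``.  Round-tripping
    through :func:`load_fixture` reproduces the beta matrix to ≤1e-9.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"not a writable directory: {directory}")
    paths = {
        "betas": directory / "betas.tsv",
        "samples": directory / "samples.csv",
        "manifest": directory / "manifest.tsv",
    }
    cohort.betas.to_csv(paths["betas"], sep="\t", index_label="probe_id",
                        float_format="%.10g")
    cohort.samples.to_csv(paths["samples"], index_label="sample_id")
    cohort.manifest.to_csv(paths["manifest"], sep="\t", index_label="probe_id")
    if cohort.detection_p is not None:
        paths["detection_p"] = directory / "detection_p.tsv"
        cohort.detection_p.to_csv(paths["detection_p"], sep="\t",
                                  index_label="probe_id", float_format="%.10g")
    if truth is not None:
        paths["truth"] = directory / "truth.json"
        paths["truth"].write_text(truth.to_json())
    return paths


def load_fixture(directory: str | Path) -> tuple[MethylationCohort, GroundTruth | None]:
    """Read a cohort written by :func:`export_fixture`."""
    directory = Path(directory)
    betas = pd.read_csv(directory / "betas.tsv", sep="\t", index_col="probe_id")
    samples = pd.read_csv(directory / "samples.csv", index_col="sample_id")
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t", index_col="probe_id",
                           keep_default_na=False, na_values=[])
    manifest["gene"] = manifest["gene"].astype(str)
    detp_path = directory / "detection_p.tsv"
    detection_p = (pd.read_csv(detp_path, sep="\t", index_col="probe_id")
                   if detp_path.exists() else None)
    truth_path = directory / "truth.json"
    truth = GroundTruth.from_json(truth_path.read_text()) if truth_path.exists() else None
    return MethylationCohort(betas, samples, manifest, detection_p), truth
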
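"""Core data containers shared across the pipeline.

The containers are thin wrappers around pandas objects so that every stage
can be inspected, written to plain-text formats, and re-loaded without loss.
Intensity tables are stored with features as rows and a (sample, replicate)
MultiIndex over columns; missing measurements are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HILIC_POS = "HILIC+"
C18_NEG = "C18-"
MODES = (HILIC_POS, C18_NEG)

N_REPLICATES = 3


@dataclass
class RawFeatureTable:
    """Replicate-level feature intensities for one or both chromatography modes.

    Attributes
    ----------
    features : DataFrame indexed by feature_id with columns ``mz`` (Da),
        ``rt`` (seconds) and ``mode`` (one of ``HILIC+`` / ``C18-``).
    intensities : DataFrame indexed by feature_id; columns are a MultiIndex
        of (sample_id, replicate) with replicate in 1..3. NaN marks a missing
        injection value.
    batches : Series mapping sample_id -> batch label.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    batches: pd.Series

    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def sample_ids(self) -> list:
        return list(self.intensities.columns.get_level_values(0).unique())

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("feature metadata and intensity rows disagree")
        reps = self.intensities.columns.get_level_values(1)
        if not set(reps) <= {1, 2, 3}:
            raise ValueError("replicate index must be in 1..3")
        per_sample = pd.Series(
            self.intensities.columns.get_level_values(0)
        ).value_counts()
        if not (per_sample == N_REPLICATES).all():
            bad = per_sample[per_sample != N_REPLICATES].index.tolist()
            raise ValueError(f"samples without exactly 3 replicate slots: {bad}")
        vals = self.intensities.to_numpy(float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("intensities must be nonnegative where present")
        bad_modes = set(self.features["mode"]) - set(MODES)
        if bad_modes:
            raise ValueError(f"unknown chromatography modes: {bad_modes}")
        missing = set(self.sample_ids) - set(self.batches.index)
        if missing:
            raise ValueError(f"samples without batch labels: {sorted(missing)}")

    def subset_mode(self, mode: str) -> "RawFeatureTable":
        keep = self.features["mode"] == mode
        return RawFeatureTable(
            self.features.loc[keep], self.intensities.loc[keep], self.batches
        )

    def to_tsv(self, path) -> None:
        """Write the schema feature_id, mz, rt, mode, batch row, sample_rep cols."""
        flat = self.intensities.copy()
        flat.columns = [f"{s}_r{r}" for s, r in flat.columns]
        out = pd.concat([self.features, flat], axis=1)
        out.index.name = "feature_id"
        with open(path, "w") as fh:
            fh.write("#batches\t" + "\t".join(
                f"{s}={b}" for s, b in self.batches.items()) + "\n")
            out.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "RawFeatureTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("#batches\t"):
                raise ValueError(f"{path}: missing #batches header line")
            pairs = [p.split("=", 1) for p in header.split("\t")[1:]]
            batches = pd.Series({s: b for s, b in pairs}, name="batch")
            table = pd.read_csv(fh, sep="\t", index_col="feature_id")
        features = table[["mz", "rt", "mode"]]
        inten = table.drop(columns=["mz", "rt", "mode"])
        cols = []
        for c in inten.columns:
            sample, rep = c.rsplit("_r", 1)
            cols.append((sample, int(rep)))
        inten.columns = pd.MultiIndex.from_tuples(cols, names=["sample", "replicate"])
        return cls(features, inten, batches)


@dataclass
class MetaboliteLibrary:
    """Level-1 identification library: name, mz, rt, mode, adduct, hmdb_id."""

    entries: pd.DataFrame

    REQUIRED = ("name", "mz", "rt", "mode", "adduct", "hmdb_id")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.entries.columns)
        if missing:
            raise ValueError(f"library missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        self.entries.loc[:, list(self.REQUIRED)].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MetaboliteLibrary":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites matrix with per-metabolite annotations.

    ``data`` rows are samples, columns are metabolite identifiers (HMDB
    accessions once annotated). ``annotations`` is indexed by the same
    metabolite identifiers with columns name, mz, rt, mode, adduct, hmdb_id.
    """

    data: pd.DataFrame
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    def validate_standardized(self, atol: float = 1e-9) -> None:
        vals = self.data.to_numpy(float)
        if np.isnan(vals).any():
            raise ValueError("standardized matrix contains missing values")
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        if np.abs(mean).max() > atol:
            raise ValueError("columns are not centered")
        if np.abs(sd - 1).max() > atol:
            raise ValueError("columns do not have unit sample SD")

    def to_tsv(self, path, annotation_path=None) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")
        if annotation_path is not None:
            self.annotations.to_csv(annotation_path, sep="\t",
                                    index_label="metabolite_id")

    @classmethod
    def from_tsv(cls, path, annotation_path=None) -> "MetaboliteMatrix":
        data = pd.read_csv(path, sep="\t", index_col="sample_id")
        ann = pd.DataFrame()
        if annotation_path is not None:
            ann = pd.read_csv(annotation_path, sep="\t", index_col="metabolite_id")
        return cls(data, ann)


PathwayMap = dict  # pathway name -> set of HMDB accessions
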
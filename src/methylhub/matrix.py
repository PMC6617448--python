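"""Paired tumor/normal feature matrices.

A :class:`PairedMatrix` is the one in-memory container used for both
methylation beta values (probes x samples, values in [0, 1]) and expression
(genes x samples, non-negative).  Pairing metadata maps every sample to a
pair identifier and a tumor/normal status; every pair must contribute
exactly one tumor and one normal sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class PairedMatrix:
    """Feature x sample matrix with tumor/normal pairing metadata.

    Parameters
    ----------
    values
        DataFrame, rows = feature ids (probes or genes), columns = sample ids.
    pairing
        DataFrame indexed by sample id with columns ``pair_id`` and
        ``status`` (``"tumor"`` or ``"normal"``).  Must cover every column
        of ``values``.
    """

    values: pd.DataFrame
    pairing: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature ids: {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.pairing.index]
        if missing:
            raise ValueError(f"samples without pairing metadata: {missing[:5]}")
        self.pairing = self.pairing.loc[list(self.values.columns)]
        bad = set(self.pairing["status"]) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown sample status values: {sorted(bad)}")
        counts = self.pairing.groupby("pair_id")["status"].value_counts().unstack(fill_value=0)
        if not ((counts.get(TUMOR, 0) == 1).all() and (counts.get(NORMAL, 0) == 1).all()):
            raise ValueError("every pair id must map to exactly one tumor and one normal sample")

    # ------------------------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_pairs(self) -> int:
        return self.pairing["pair_id"].nunique()

    def paired_samples(self) -> tuple[list[str], list[str]]:
        """Tumor and normal sample ids in matching pair order."""
        by_pair = self.pairing.reset_index().pivot(
            index="pair_id", columns="status", values=self.pairing.index.name or "index"
        )
        return list(by_pair[TUMOR]), list(by_pair[NORMAL])

    def tumor_normal_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(features x pairs) value arrays for tumor and normal, pair-aligned."""
        t, n = self.paired_samples()
        return self.values[t].to_numpy(float), self.values[n].to_numpy(float)

    def subset_features(self, keep: list[str] | pd.Index | np.ndarray) -> "PairedMatrix":
        return PairedMatrix(self.values.loc[keep], self.pairing.copy())

    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write with a two-row header: sample ids, then ``pair_id:status``."""
        with open(path, "w") as fh:
            fh.write("feature_id\t" + "\t".join(map(str, self.values.columns)) + "\n")
            tags = [
                f"{self.pairing.loc[s, 'pair_id']}:{self.pairing.loc[s, 'status']}"
                for s in self.values.columns
            ]
            fh.write("pairing\t" + "\t".join(tags) + "\n")
            self.values.to_csv(fh, sep="\t", header=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "PairedMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            tagline = fh.readline().rstrip("\n").split("\t")
            if not tagline or tagline[0] != "pairing":
                raise ValueError(f"{path}: second header row must start with 'pairing'")
            values = pd.read_csv(
                fh, sep="\t", header=None, names=header, index_col=0, na_values=["NA"]
            )
        samples = header[1:]
        pairs, statuses = [], []
        for tag in tagline[1:]:
            pair_id, _, status = tag.rpartition(":")
            pairs.append(pair_id)
            statuses.append(status)
        pairing = pd.DataFrame({"pair_id": pairs, "status": statuses}, index=pd.Index(samples, name="sample"))
        return cls(values, pairing)
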
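"""PSM containers and tab-delimited input/output.

The input dialect follows the de facto standard tab-separated PSM feature
table: a header line ``SpecId<TAB>Label<TAB>ScanNr<TAB><features...>`` with
optional trailing ``Peptide`` and ``Proteins`` columns, then one row per
PSM.  ``Label`` is +1 for a target PSM and -1 for a decoy PSM; any other
value is an error, because a silently misparsed label corrupts every FDR
estimate downstream.  Feature cells must be finite numbers; missing values
are rejected rather than imputed.

Results are written as a tab-separated table (PSMId, Label, score, q-value,
peptide) sorted by descending score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


__all__ = [
    "PSMRecord",
    "PSMDataset",
    "PinFormatError",
    "read_pin",
    "write_results",
    "read_results",
]

_ID_COL = "SpecId"
_LABEL_COL = "Label"
_SCAN_COL = "ScanNr"
_OPTIONAL_TRAILING = ("Peptide", "Proteins")


class PinFormatError(ValueError):
    """Raised when a PSM feature table violates the expected dialect."""


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match.

    ``features`` is the fixed-length real-valued descriptor vector of the
    match; ``is_decoy`` marks matches against the decoy database.  PSMs
    sharing a ``spectrum_id`` came from the same spectrum and must travel
    together through any train/validation split.  ``fold``, when set, is
    the 1-based cross-validation subset tag.
    """

    psm_id: str
    spectrum_id: str
    is_decoy: bool
    features: np.ndarray
    fold: int | None = None
    peptide: str | None = None

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float).ravel()
        if not np.all(np.isfinite(feats)):
            raise ValueError(f"PSM {self.psm_id!r}: non-finite feature value")
        object.__setattr__(self, "features", feats)


@dataclass
class PSMDataset:
    """A uniform collection of PSMs with named features.

    Internally column-oriented (one numpy matrix of features plus aligned
    id/label arrays) for efficient scoring; :meth:`records` iterates as
    :class:`PSMRecord` values when row-wise access is convenient.
    """

    psm_ids: np.ndarray
    spectrum_ids: np.ndarray
    is_decoy: np.ndarray
    features: np.ndarray
    feature_names: list[str]
    peptides: np.ndarray | None = None
    k: int = 3
    folds: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.psm_ids = np.asarray(self.psm_ids, dtype=object)
        self.spectrum_ids = np.asarray(self.spectrum_ids, dtype=object)
        self.is_decoy = np.asarray(self.is_decoy, dtype=bool)
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n = len(self.psm_ids)
        if not (len(self.spectrum_ids) == len(self.is_decoy) == self.features.shape[0] == n):
            raise ValueError("psm_ids, spectrum_ids, is_decoy and features must align")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature matrix has {self.features.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature matrix contains non-finite values")
        if len(set(self.psm_ids.tolist())) != n:
            raise ValueError("psm_id values must be unique")
        if self.folds is not None:
            self.folds = np.asarray(self.folds, dtype=int)
            if len(self.folds) != n:
                raise ValueError("folds must align with records")
            bad = (self.folds < 1) | (self.folds > self.k)
            if bad.any():
                raise ValueError(f"fold tags must lie in 1..{self.k}")

    # -- basic views -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.psm_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_targets(self) -> int:
        return int(np.count_nonzero(~self.is_decoy))

    @property
    def n_decoys(self) -> int:
        return int(np.count_nonzero(self.is_decoy))

    def require_both_labels(self) -> None:
        """Statistics need at least one target and one decoy."""
        if self.n_targets == 0 or self.n_decoys == 0:
            raise ValueError(
                f"dataset needs both targets and decoys "
                f"(got {self.n_targets} targets, {self.n_decoys} decoys)"
            )

    def records(self) -> Iterable[PSMRecord]:
        for i in range(len(self)):
            yield PSMRecord(
                psm_id=str(self.psm_ids[i]),
                spectrum_id=str(self.spectrum_ids[i]),
                is_decoy=bool(self.is_decoy[i]),
                features=self.features[i],
                fold=None if self.folds is None else int(self.folds[i]),
                peptide=None if self.peptides is None else str(self.peptides[i]),
            )

    @classmethod
    def from_records(
        cls, records: Sequence[PSMRecord], feature_names: Sequence[str], k: int = 3
    ) -> "PSMDataset":
        records = list(records)
        n_feat = len(feature_names)
        for rec in records:
            if rec.features.size != n_feat:
                raise ValueError(
                    f"PSM {rec.psm_id!r} has {rec.features.size} features, expected {n_feat}"
                )
        feats = (
            np.array([r.features for r in records], dtype=float)
            if records
            else np.empty((0, n_feat))
        )
        peptides = None
        if any(r.peptide is not None for r in records):
            peptides = np.asarray([r.peptide or "" for r in records], dtype=object)
        folds = None
        if records and all(r.fold is not None for r in records):
            folds = np.asarray([r.fold for r in records], dtype=int)
        return cls(
            psm_ids=np.asarray([r.psm_id for r in records], dtype=object),
            spectrum_ids=np.asarray([r.spectrum_id for r in records], dtype=object),
            is_decoy=np.asarray([r.is_decoy for r in records], dtype=bool),
            features=feats,
            feature_names=list(feature_names),
            peptides=peptides,
            k=k,
            folds=folds,
        )

    def subset(self, mask_or_index) -> "PSMDataset":
        """Row subset preserving order; accepts a boolean mask or index array."""
        idx = np.asarray(mask_or_index)
        return PSMDataset(
            psm_ids=self.psm_ids[idx],
            spectrum_ids=self.spectrum_ids[idx],
            is_decoy=self.is_decoy[idx],
            features=self.features[idx],
            feature_names=self.feature_names,
            peptides=None if self.peptides is None else self.peptides[idx],
            k=self.k,
            folds=None if self.folds is None else self.folds[idx],
        )


# ---------------------------------------------------------------------------
# reading


def read_pin(path) -> PSMDataset:
    """Read a tab-delimited PSM feature table.

    Expects the header ``SpecId  Label  ScanNr  <features...>`` with
    optional trailing ``Peptide`` and ``Proteins`` columns.  ``ScanNr``
    doubles as the spectrum identifier.  Errors name the offending column
    (header problems) or row and column (cell problems).
    """
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise PinFormatError(f"{path}: empty file, expected a header line")
    header = header_line.rstrip("\n").split("\t")

    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise PinFormatError(f"{path}: duplicate header column {col!r}")
        seen.add(col)
    for required in (_ID_COL, _LABEL_COL, _SCAN_COL):
        if required not in seen:
            raise PinFormatError(f"{path}: missing required header column {required!r}")

    reserved = {_ID_COL, _LABEL_COL, _SCAN_COL, *_OPTIONAL_TRAILING}
    feature_names = [c for c in header if c not in reserved]
    if not feature_names:
        raise PinFormatError(f"{path}: no feature columns found in header")

    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.empty:
        return PSMDataset(
            psm_ids=np.empty(0, dtype=object),
            spectrum_ids=np.empty(0, dtype=object),
            is_decoy=np.empty(0, dtype=bool),
            features=np.empty((0, len(feature_names))),
            feature_names=feature_names,
        )

    labels_raw = df[_LABEL_COL].to_numpy()
    is_decoy = np.empty(len(df), dtype=bool)
    for i, raw in enumerate(labels_raw):
        if raw == "1":
            is_decoy[i] = False
        elif raw == "-1":
            is_decoy[i] = True
        else:
            raise PinFormatError(
                f"{path}: row {i + 1}, column {_LABEL_COL!r}: "
                f"label must be 1 or -1, got {raw!r}"
            )

    feats = np.empty((len(df), len(feature_names)))
    for j, name in enumerate(feature_names):
        col = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(col)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise PinFormatError(
                f"{path}: row {row + 1}, column {name!r}: "
                f"non-numeric feature value {df[name].iloc[row]!r}"
            )
        feats[:, j] = col

    peptides = (
        df["Peptide"].to_numpy(dtype=object) if "Peptide" in df.columns else None
    )
    return PSMDataset(
        psm_ids=df[_ID_COL].to_numpy(dtype=object),
        spectrum_ids=df[_SCAN_COL].to_numpy(dtype=object),
        is_decoy=is_decoy,
        features=feats,
        feature_names=feature_names,
        peptides=peptides,
    )


# ---------------------------------------------------------------------------
# writing


def write_results(results: pd.DataFrame, path) -> None:
    """Write a final rescoring table, sorted by descending score.

    ``results`` must have columns ``psm_id``, ``is_decoy``, ``score`` and
    ``qvalue`` (``peptide`` optional).  The on-disk table encodes the label
    as +1 (target) / -1 (decoy) and prints floats with enough digits that a
    round-trip read reproduces them to 1e-6.
    """
    required = {"psm_id", "is_decoy", "score", "qvalue"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    q = results["qvalue"].to_numpy(dtype=float)
    if len(q) and (np.nanmin(q) < 0 or np.nanmax(q) > 1):
        raise ValueError("q-values must lie in [0, 1]")

    out = pd.DataFrame(
        {
            "PSMId": results["psm_id"].to_numpy(),
            "Label": np.where(results["is_decoy"].to_numpy(dtype=bool), -1, 1),
            "score": results["score"].to_numpy(dtype=float),
            "q-value": q,
            "peptide": (
                results["peptide"].to_numpy()
                if "peptide" in results.columns
                else np.full(len(results), "", dtype=object)
            ),
        }
    )
    out = out.sort_values("score", ascending=False, kind="stable")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    return pd.DataFrame(
        {
            "psm_id": df["PSMId"].astype(str),
            "is_decoy": df["Label"].astype(int) == -1,
            "score": df["score"].astype(float),
            "qvalue": df["q-value"].astype(float),
            "peptide": df["peptide"].astype(str) if "peptide" in df.columns else "",
        }
    )
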
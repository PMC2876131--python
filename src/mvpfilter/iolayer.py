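"""Tabular I/O for methylation-array artifacts.

All on-disk formats are plain TSV with a header row:

* beta matrix — ``probe_id<TAB>S1<TAB>S2...``, one probe per row, values in
  [0, 1]; empty cells or ``NA`` mark missing measurements.
* signal table (long) — ``sample_id<TAB>probe_id<TAB>cy3<TAB>cy5``; an
  optional per-sample sidecar carries ``sample_id conversion_score
  background_cy3 background_cy5``.
* replicate design — ``pair_id<TAB>sample_rep1<TAB>sample_rep2``.
* outcomes — ``sample_id<TAB><outcome1><TAB><outcome2>...``.

Readers enforce the invariants of each container and raise
:class:`FormatError` / :class:`ValidationError` naming the offending row or
identifier, so malformed inputs fail loudly at the boundary rather than
deep inside an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "BetaMatrix",
    "SignalTable",
    "ReplicateDesign",
    "OutcomeTable",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_signal_table",
    "read_replicate_design",
    "read_outcomes",
]

# float formatting used by every writer; round-trips at 10 significant digits
_FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Structurally malformed input (duplicates, bad header, wrong columns)."""


class ValidationError(ValueError):
    """Well-formed input whose values violate a container invariant."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups}")


@dataclass
class BetaMatrix:
    """Methylation fractions, probes as rows and samples as columns.

    ``data`` is a float DataFrame indexed by probe ID with sample-ID
    columns; missing measurements are NaN. Every non-missing value lies in
    [0, 1].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe IDs")
        _check_unique(self.data.columns, "sample IDs")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {vals[i, j]!r} out of [0, 1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        """Raw probe × sample array (NaN = missing)."""
        return self.data.to_numpy()


@dataclass
class SignalTable:
    """Two-channel fluorescence records, one row per (sample, probe).

    ``records`` has columns ``sample_id, probe_id, cy3, cy5`` where Cy3 is
    the unmethylated-allele intensity and Cy5 the methylated-allele
    intensity (arbitrary units, >= 0). ``sample_info``, if given, is
    indexed by sample ID with optional ``conversion_score``,
    ``background_cy3`` and ``background_cy5`` columns.
    """

    records: pd.DataFrame
    sample_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = ["sample_id", "probe_id", "cy3", "cy5"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise FormatError(f"signal table lacks columns {missing}")
        dup = self.records.duplicated(subset=["sample_id", "probe_id"])
        if dup.any():
            row = self.records[dup].iloc[0]
            raise FormatError(
                f"duplicate signal record for sample {row['sample_id']!r}, "
                f"probe {row['probe_id']!r}"
            )
        for ch in ("cy3", "cy5"):
            col = self.records[ch].to_numpy(dtype=float)
            if not np.isfinite(col).all():
                raise ValidationError(f"non-finite {ch} intensity present")
            if (col < 0).any():
                i = int(np.argmax(col < 0))
                row = self.records.iloc[i]
                raise ValidationError(
                    f"negative {ch} intensity {col[i]} for sample "
                    f"{row['sample_id']!r}, probe {row['probe_id']!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.records["sample_id"]))

    @property
    def probe_ids(self) -> list[str]:
        return list(pd.unique(self.records["probe_id"]))


@dataclass
class ReplicateDesign:
    """Pairing of sample IDs assayed twice (technical replicates, k = 1, 2)."""

    pairs: pd.DataFrame  # columns: pair_id, sample_rep1, sample_rep2

    def __post_init__(self) -> None:
        required = ["pair_id", "sample_rep1", "sample_rep2"]
        missing = [c for c in required if c not in self.pairs.columns]
        if missing:
            raise FormatError(f"replicate design lacks columns {missing}")
        _check_unique(self.pairs["pair_id"], "pair IDs")
        slots = pd.concat([self.pairs["sample_rep1"], self.pairs["sample_rep2"]])
        if slots.duplicated().any():
            dup = slots[slots.duplicated()].iloc[0]
            raise ValidationError(
                f"sample {dup!r} appears in more than one replicate slot"
            )

    def __len__(self) -> int:
        return len(self.pairs)

    def check_against(self, betas: BetaMatrix) -> None:
        """Raise if any design sample is absent from the beta matrix."""
        have = set(betas.sample_ids)
        need = set(self.pairs["sample_rep1"]) | set(self.pairs["sample_rep2"])
        absent = sorted(need - have)
        if absent:
            raise ValidationError(
                f"replicate design references samples missing from the "
                f"beta matrix: {absent}"
            )


@dataclass
class OutcomeTable:
    """Continuous outcomes, one row per sample and one column per outcome.

    ``causal_probes`` is populated by the synthetic generator to record
    which probes truly drive each simulated outcome; it is empty for
    outcomes read from disk.
    """

    data: pd.DataFrame
    causal_probes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample IDs")
        vals = self.data.to_numpy(dtype=float)
        inf = np.isinf(vals)
        if inf.any():
            i, j = np.argwhere(inf)[0]
            raise ValidationError(
                f"non-finite outcome at sample {self.data.index[i]!r}, "
                f"outcome {self.data.columns[j]!r}"
            )

    @property
    def outcome_names(self) -> list[str]:
        return list(self.data.columns)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown outcome {name!r}; have {self.outcome_names}")
        return self.data[name]


# ---------------------------------------------------------------------------
# readers / writers


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probe × sample beta matrix from TSV.

    Empty cells and ``NA`` become missing values. Duplicated probe or
    sample IDs raise :class:`FormatError`; values outside [0, 1] raise
    :class:`ValidationError` naming the probe and sample.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={0: str}, na_values=["NA"], keep_default_na=False
    )
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected probe_id column plus >=1 sample")
    df = df.set_index(df.columns[0])
    df.index.name = "probe_id"
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric beta value ({exc})") from exc
    return BetaMatrix(df)


def write_beta_matrix(betas: BetaMatrix, path: str | Path) -> None:
    betas.data.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="NA")


def read_signal_table(
    path: str | Path, controls_path: str | Path | None = None
) -> SignalTable:
    """Read a long-format two-channel signal table, plus optional per-sample
    sidecar with conversion scores and negative-control backgrounds."""
    rec = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "probe_id": str})
    info = None
    if controls_path is not None:
        info = pd.read_csv(controls_path, sep="\t", dtype={"sample_id": str})
        if "sample_id" not in info.columns:
            raise FormatError(f"{controls_path}: lacks sample_id column")
        _check_unique(info["sample_id"], "sample IDs in controls sidecar")
        info = info.set_index("sample_id")
    return SignalTable(rec, info)


def read_replicate_design(path: str | Path) -> ReplicateDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ReplicateDesign(df)


def read_outcomes(path: str | Path) -> OutcomeTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"],
                     keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: outcomes file lacks sample_id column")
    df = df.set_index("sample_id")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric outcome value ({exc})") from exc
    return OutcomeTable(df)
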
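"""Tabular I/O and container types for MSAP analyses.

An MSAP assay digests genomic DNA in two parallel reactions, EcoRI/HpaII and
EcoRI/MspI, and scores each amplified fragment (locus) as present (1) or
absent (0) in each lane for every sample.  This module defines the in-memory
containers for those presence/absence matrices, for called methylation-state
matrices, and for companion expression tables, plus strict TSV readers and
writers for each.

File dialect is fixed: tab separator, UTF-8, "." decimal point, no quoting.
Missing values are not allowed — every locus is scored in every lane — and an
explicit NA token is rejected with a coordinate-bearing message.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CellValueError, ConfigError, DuplicateIdError, FormatError

STATE_TOKENS = ("NON", "HEMI", "FULL", "UNINF")

_NA_TOKENS = {"", "NA", "NaN", "nan", "N/A", "null", "None"}


@dataclasses.dataclass(frozen=True)
class LocusMeta:
    """Identity and assay provenance of one MSAP locus.

    Parameters
    ----------
    locus_id
        Unique locus label within a matrix.
    primer_pair
        Selective-amplification primer combination that produced the band
        (e.g. ``"E65+H/M33"``).  Empty string when unknown.
    fragment_length
        Band length in base pairs, or ``None`` when unknown.  Typical MSAP
        fragments run 55-550 bp but the range is advisory, not enforced.
    """

    locus_id: str
    primer_pair: str = ""
    fragment_length: int | None = None

    def __post_init__(self) -> None:
        if self.fragment_length is not None and self.fragment_length <= 0:
            raise ValueError(
                f"locus {self.locus_id!r}: fragment_length must be > 0, "
                f"got {self.fragment_length}"
            )


def _check_unique(labels: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise DuplicateIdError(f"duplicate {kind}: {lab!r}")
        seen.add(lab)


@dataclasses.dataclass
class BandMatrix:
    """Loci x samples presence calls for the two enzyme lanes.

    ``h_lane`` holds the EcoRI/HpaII digest, ``m_lane`` the EcoRI/MspI
    digest; both are 0/1 integer DataFrames indexed by locus_id with one
    column per sample.
    """

    loci: list[LocusMeta]
    h_lane: pd.DataFrame
    m_lane: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def samples(self) -> list[str]:
        return list(self.h_lane.columns)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def validate(self) -> None:
        _check_unique(self.locus_ids, "locus_id")
        _check_unique(list(self.h_lane.columns), "sample label")
        if self.h_lane.shape != self.m_lane.shape:
            raise FormatError(
                f"lane shapes differ: HpaII {self.h_lane.shape} vs "
                f"MspI {self.m_lane.shape}"
            )
        if list(self.h_lane.columns) != list(self.m_lane.columns):
            raise FormatError("lane sample columns differ between HpaII and MspI")
        if list(self.h_lane.index) != self.locus_ids or list(self.m_lane.index) != self.locus_ids:
            raise FormatError("lane row index does not match locus metadata")
        for name, lane in (("HpaII", self.h_lane), ("MspI", self.m_lane)):
            vals = lane.to_numpy()
            bad = ~np.isin(vals, (0, 1))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise CellValueError(
                    f"{name} lane: non-binary value {vals[i, j]!r} at locus "
                    f"{lane.index[i]!r}, sample {lane.columns[j]!r}"
                )


@dataclasses.dataclass
class StateMatrix:
    """Loci x samples called methylation states.

    ``states`` is a DataFrame of tokens from :data:`STATE_TOKENS`
    (NON, HEMI, FULL, UNINF), indexed by locus_id with one column per sample.
    """

    loci: list[LocusMeta]
    states: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def samples(self) -> list[str]:
        return list(self.states.columns)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def validate(self) -> None:
        _check_unique(self.locus_ids, "locus_id")
        _check_unique(list(self.states.columns), "sample label")
        if list(self.states.index) != self.locus_ids:
            raise FormatError("state row index does not match locus metadata")
        vals = self.states.to_numpy()
        bad = ~np.isin(vals, STATE_TOKENS)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CellValueError(
                f"illegal state token {vals[i, j]!r} at locus "
                f"{self.states.index[i]!r}, sample {self.states.columns[j]!r}"
            )


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values (relative or FPKM-like)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        _check_unique(list(self.values.index), "gene_id")
        _check_unique(list(self.values.columns), "sample label")
        vals = self.values.to_numpy(dtype=float)
        if np.isnan(vals).any():
            i, j = np.argwhere(np.isnan(vals))[0]
            raise CellValueError(
                f"missing expression value at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise CellValueError(
                f"negative expression value {vals[i, j]} at gene "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )


@dataclasses.dataclass
class RunConfig:
    """Run-level configuration shared by the CLI commands.

    ``group_assignments`` maps sample labels to group labels (e.g. xylem /
    non-xylem); ``stage_paths`` lists ordered sample sequences used by the
    developmental-transition analysis.  Sample order in input files is
    authoritative for stage-path defaults.
    """

    group_assignments: dict[str, str] = dataclasses.field(default_factory=dict)
    stage_paths: list[list[str]] = dataclasses.field(default_factory=list)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**{k: raw[k] for k in raw})

    def check_samples(self, samples: Sequence[str]) -> None:
        """Raise if any referenced sample is absent from *samples*."""
        have = set(samples)
        for s in self.group_assignments:
            if s not in have:
                raise ConfigError(f"group assignment references unknown sample {s!r}")
        for path in self.stage_paths:
            for s in path:
                if s not in have:
                    raise ConfigError(f"stage path references unknown sample {s!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_META_COLS = ("locus_id", "primer_pair", "length_bp")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                           encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def _parse_length(token: str, locus_id: str) -> int | None:
    if token in _NA_TOKENS:
        return None
    try:
        value = int(token)
    except ValueError as exc:
        raise CellValueError(
            f"locus {locus_id!r}: length_bp must be an integer, got {token!r}"
        ) from exc
    if value <= 0:
        raise CellValueError(f"locus {locus_id!r}: length_bp must be > 0, got {value}")
    return value


def _parse_binary(df: pd.DataFrame, columns: Sequence[str], lane: str) -> pd.DataFrame:
    out = np.empty((len(df), len(columns)), dtype=np.int8)
    for j, col in enumerate(columns):
        for i, token in enumerate(df[col]):
            if token in _NA_TOKENS:
                raise CellValueError(
                    f"missing value at locus {df['locus_id'].iat[i]!r}, column "
                    f"{col!r}: NA band calls are not allowed — every locus must "
                    f"be scored in every lane"
                )
            if token not in ("0", "1"):
                raise CellValueError(
                    f"non-binary value {token!r} at locus {df['locus_id'].iat[i]!r}, "
                    f"column {col!r} ({lane} lane)"
                )
            out[i, j] = int(token)
    samples = [c[:-2] for c in columns]
    return pd.DataFrame(out, index=list(df["locus_id"]), columns=samples)


def read_band_matrix(path: str | Path) -> BandMatrix:
    """Read a dual-lane band table.

    Expected header: ``locus_id, primer_pair, length_bp`` followed by two
    columns ``<sample>.H`` and ``<sample>.M`` per sample holding 0/1 presence
    calls for the EcoRI/HpaII and EcoRI/MspI digests.
    """
    df = _read_tsv(path)
    cols = list(df.columns)
    if cols[: len(_META_COLS)] != list(_META_COLS):
        raise FormatError(
            f"{path}: header must start with {_META_COLS}, got {cols[:3]}"
        )
    lane_cols = cols[len(_META_COLS):]
    h_cols = [c for c in lane_cols if c.endswith(".H")]
    m_cols = [c for c in lane_cols if c.endswith(".M")]
    stray = [c for c in lane_cols if not (c.endswith(".H") or c.endswith(".M"))]
    if stray:
        raise FormatError(f"{path}: unrecognized column {stray[0]!r} "
                          f"(expected '<sample>.H' or '<sample>.M')")
    h_samples = [c[:-2] for c in h_cols]
    m_samples = [c[:-2] for c in m_cols]
    if h_samples != m_samples:
        missing_m = [s for s in h_samples if s not in m_samples]
        missing_h = [s for s in m_samples if s not in h_samples]
        if missing_m:
            raise FormatError(f"{path}: missing column {missing_m[0] + '.M'!r}")
        if missing_h:
            raise FormatError(f"{path}: missing column {missing_h[0] + '.H'!r}")
        raise FormatError(f"{path}: lane columns out of order; expected paired "
                          f"'<sample>.H'/'<sample>.M' in matching sample order")
    if not h_samples:
        raise FormatError(f"{path}: no sample lane columns found")
    _check_unique(list(df["locus_id"]), "locus_id")
    loci = [
        LocusMeta(row.locus_id, row.primer_pair,
                  _parse_length(row.length_bp, row.locus_id))
        for row in df.itertuples(index=False)
    ]
    h = _parse_binary(df, h_cols, "HpaII")
    m = _parse_binary(df, m_cols, "MspI")
    return BandMatrix(loci=loci, h_lane=h, m_lane=m)


def write_band_matrix(bands: BandMatrix, path: str | Path) -> None:
    """Write a :class:`BandMatrix` in the format read by :func:`read_band_matrix`."""
    out = pd.DataFrame({
        "locus_id": bands.locus_ids,
        "primer_pair": [l.primer_pair for l in bands.loci],
        "length_bp": ["" if l.fragment_length is None else str(l.fragment_length)
                      for l in bands.loci],
    })
    for s in bands.samples:
        out[f"{s}.H"] = bands.h_lane[s].to_numpy()
        out[f"{s}.M"] = bands.m_lane[s].to_numpy()
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_state_matrix(path: str | Path) -> StateMatrix:
    """Read a called-state table written by :func:`write_state_matrix`."""
    df = _read_tsv(path)
    cols = list(df.columns)
    if cols[: len(_META_COLS)] != list(_META_COLS):
        raise FormatError(
            f"{path}: header must start with {_META_COLS}, got {cols[:3]}"
        )
    sample_cols = cols[len(_META_COLS):]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    _check_unique(list(df["locus_id"]), "locus_id")
    loci = [
        LocusMeta(row.locus_id, row.primer_pair,
                  _parse_length(row.length_bp, row.locus_id))
        for row in df.itertuples(index=False)
    ]
    for col in sample_cols:
        for i, token in enumerate(df[col]):
            if token not in STATE_TOKENS:
                raise CellValueError(
                    f"illegal state token {token!r} at locus "
                    f"{df['locus_id'].iat[i]!r}, sample {col!r}"
                )
    states = pd.DataFrame(
        {s: df[s].to_numpy() for s in sample_cols}, index=list(df["locus_id"])
    )
    return StateMatrix(loci=loci, states=states)


def write_state_matrix(states: StateMatrix, path: str | Path) -> None:
    """Write a :class:`StateMatrix`; read-back is a bit-exact roundtrip."""
    out = pd.DataFrame({
        "locus_id": states.locus_ids,
        "primer_pair": [l.primer_pair for l in states.loci],
        "length_bp": ["" if l.fragment_length is None else str(l.fragment_length)
                      for l in states.loci],
    })
    for s in states.samples:
        out[s] = states.states[s].to_numpy()
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample expression table (gene_id column then samples)."""
    df = _read_tsv(path)
    cols = list(df.columns)
    if not cols or cols[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got "
                          f"{cols[0] if cols else 'nothing'}")
    sample_cols = cols[1:]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    if len(df) == 0:
        raise FormatError(f"{path}: empty table (no genes)")
    _check_unique(list(df["gene_id"]), "gene_id")
    values = np.empty((len(df), len(sample_cols)), dtype=float)
    for j, col in enumerate(sample_cols):
        for i, token in enumerate(df[col]):
            if token in _NA_TOKENS:
                raise CellValueError(
                    f"missing expression value at gene {df['gene_id'].iat[i]!r}, "
                    f"sample {col!r}"
                )
            try:
                v = float(token)
            except ValueError as exc:
                raise CellValueError(
                    f"non-numeric expression value {token!r} at gene "
                    f"{df['gene_id'].iat[i]!r}, sample {col!r}"
                ) from exc
            if v < 0:
                raise CellValueError(
                    f"negative expression value {v} at gene "
                    f"{df['gene_id'].iat[i]!r}, sample {col!r}"
                )
            values[i, j] = v
    return ExpressionMatrix(
        pd.DataFrame(values, index=list(df["gene_id"]), columns=sample_cols)
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_run_summary(path: str | Path, payload: Mapping) -> None:
    """Write a JSON run summary (counts, parameters, versions)."""
    from . import __version__

    doc = {"msapkit_version": __version__, **payload}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")
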
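"""Ct (threshold-cycle) data model, file I/O, validation and subsetting.

The central container is :class:`CtMatrix`: a genes x samples table of Ct
values (``NaN`` marks a missing well) together with per-sample metadata
(experimental group, tissue, time point) and a per-gene role flag
(``candidate_reference`` or ``target``).  Ct and Cp (crossing point) are
treated as the same quantity.

Two file dialects are supported, both CSV or TSV (delimiter sniffed):

* **long** -- one row per (sample, gene) with columns
  ``sample,gene,ct[,group,tissue,timepoint]``;
* **wide** -- first column ``gene``, remaining columns sample ids, with a
  metadata sidecar ``sample,group[,tissue,timepoint]``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

#: Hard bounds for a plausible threshold cycle (40-45-cycle instruments with headroom).
CT_MIN = 0.0
CT_MAX = 50.0
#: Ct above this indicates low expression; flagged with a warning, not rejected.
CT_LOW_EXPRESSION = 35.0

ROLE_REFERENCE = "candidate_reference"
ROLE_TARGET = "target"

_META_COLUMNS = ("group", "tissue", "timepoint")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for a single sample (animal x tissue x time point)."""

    sample_id: str
    group: str
    tissue: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be a non-empty string")
        if not self.group:
            raise ValidationError(f"sample {self.sample_id!r}: group label must be non-empty")


@dataclass
class CtMatrix:
    """Genes x samples threshold-cycle matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene, columns are sample ids; ``NaN`` = missing.
    meta
        DataFrame indexed by sample id with columns ``group``, ``tissue``,
        ``timepoint`` (the latter two may be empty strings).
    roles
        Per-gene role, ``candidate_reference`` (default) or ``target``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    roles: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        meta = self.meta.copy()
        for col in _META_COLUMNS:
            if col not in meta.columns:
                meta[col] = ""
        meta = meta[list(_META_COLUMNS)].fillna("").astype(str)
        self.meta = meta
        if self.roles is None:
            self.roles = pd.Series(ROLE_REFERENCE, index=self.values.index, dtype=object)
        else:
            self.roles = pd.Series(self.roles, dtype=object).reindex(self.values.index).fillna(ROLE_REFERENCE)
        self._check_alignment()

    # -- basic structure ---------------------------------------------------

    def _check_alignment(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if not self.meta.index.equals(self.values.columns):
            missing = [s for s in self.values.columns if s not in self.meta.index]
            if missing:
                raise ValidationError(f"samples without metadata: {missing}")
            self.meta = self.meta.loc[self.values.columns]
        bad = [s for s, g in self.meta["group"].items() if g == ""]
        if bad:
            raise ValidationError(f"samples with empty group label: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[SampleMeta]:
        return [
            SampleMeta(sample_id=str(s), group=row["group"], tissue=row["tissue"], timepoint=row["timepoint"])
            for s, row in self.meta.iterrows()
        ]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.meta["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def candidate_genes(self) -> list[str]:
        return [g for g in self.genes if self.roles[g] == ROLE_REFERENCE]

    def target_genes(self) -> list[str]:
        return [g for g in self.genes if self.roles[g] == ROLE_TARGET]

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.values.copy(), self.meta.copy(), self.roles.copy())

    def __eq__(self, other: object) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, CtMatrix):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.meta.equals(other.meta)
            and self.roles.equals(other.roles)
        )

    # -- subsetting ---------------------------------------------------------

    def subset(
        self,
        genes: Iterable[str] | None = None,
        groups: Iterable[str] | None = None,
        tissue: str | None = None,
        timepoint: str | None = None,
    ) -> "CtMatrix":
        """Filter by genes and/or sample metadata, preserving order.

        Raises
        ------
        ValidationError
            If a requested label does not exist or the result is empty.
        """
        values = self.values
        if genes is not None:
            genes = list(genes)
            unknown = [g for g in genes if g not in values.index]
            if unknown:
                raise ValidationError(f"unknown genes requested: {unknown}")
            keep = [g for g in self.genes if g in set(genes)]
            values = values.loc[keep]
        mask = pd.Series(True, index=self.meta.index)
        if groups is not None:
            groups = set(groups)
            unknown = groups - set(self.meta["group"])
            if unknown:
                raise ValidationError(f"unknown group labels requested: {sorted(unknown)}")
            mask &= self.meta["group"].isin(groups)
        if tissue is not None:
            if tissue not in set(self.meta["tissue"]):
                raise ValidationError(f"unknown tissue label: {tissue!r}")
            mask &= self.meta["tissue"] == tissue
        if timepoint is not None:
            if timepoint not in set(self.meta["timepoint"]):
                raise ValidationError(f"unknown timepoint label: {timepoint!r}")
            mask &= self.meta["timepoint"] == timepoint
        keep_samples = [s for s in values.columns if mask[s]]
        if len(values.index) == 0 or len(keep_samples) == 0:
            raise ValidationError("subset selects no data")
        return CtMatrix(values[keep_samples], self.meta.loc[keep_samples], self.roles.loc[values.index])

    def complete_cases(self, genes: Iterable[str] | None = None) -> "CtMatrix":
        """Drop samples with any missing Ct among the named genes.

        Stability indices and normalization factors are sample-wise products,
        so pairwise-complete handling is unsound; analyses run on complete
        cases over the panel in use.  Dropped sample ids are logged.
        """
        genes = list(genes) if genes is not None else self.genes
        unknown = [g for g in genes if g not in self.values.index]
        if unknown:
            raise ValidationError(f"unknown genes: {unknown}")
        ok = ~self.values.loc[genes].isna().any(axis=0)
        dropped = [s for s in self.sample_ids if not ok[s]]
        if dropped:
            logger.info("complete_cases: dropping samples with missing Ct: %s", dropped)
        keep = [s for s in self.sample_ids if ok[s]]
        if len(keep) < 3:
            raise ValidationError(
                f"fewer than 3 complete samples remain (kept {len(keep)}, dropped {len(dropped)})"
            )
        return CtMatrix(self.values[keep], self.meta.loc[keep], self.roles.copy())


# -- validation --------------------------------------------------------------


def validate(ct: CtMatrix) -> CtMatrix:
    """Enforce CtMatrix invariants; returns the matrix unchanged if valid.

    Every present Ct must be finite and inside ``(0, 50)``; at least 2 genes
    and 3 samples are required.  Ct above 35 triggers a low-expression
    warning without rejection.  Idempotent.
    """
    vals = ct.values.to_numpy(dtype=float)
    present = ~np.isnan(vals)
    if not np.isfinite(vals[present]).all():
        raise ValidationError("non-finite Ct value present")
    if (vals[present] <= CT_MIN).any() or (vals[present] >= CT_MAX).any():
        bad = np.argwhere(present & ((vals <= CT_MIN) | (vals >= CT_MAX)))
        g, s = bad[0]
        raise ValidationError(
            f"Ct out of bounds ({CT_MIN}, {CT_MAX}) at gene {ct.genes[g]!r}, sample {ct.sample_ids[s]!r}: "
            f"{vals[g, s]}"
        )
    if ct.n_genes < 2:
        raise ValidationError(f"need at least 2 genes, got {ct.n_genes}")
    if ct.n_samples < 3:
        raise ValidationError(f"need at least 3 samples, got {ct.n_samples}")
    n_low = int((vals[present] > CT_LOW_EXPRESSION).sum())
    if n_low:
        warnings.warn(
            f"{n_low} Ct value(s) above {CT_LOW_EXPRESSION} (low expression); retained",
            UserWarning,
            stacklevel=2,
        )
    return ct


# -- file I/O ----------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def _parse_ct_column(raw: pd.Series, context: pd.DataFrame) -> pd.Series:
    ct = pd.to_numeric(raw, errors="coerce")
    # entries that are textual but not a recognised NA token are hard errors
    na_tokens = {"", "na", "nan", "n/a", "none", "nd", "null"}
    is_na_token = raw.isna() | raw.astype(str).str.strip().str.lower().isin(na_tokens)
    bad = ct.isna() & ~is_na_token
    if bad.any():
        i = bad[bad].index[0]
        raise InputError(
            f"unparseable Ct value {raw[i]!r} at sample {context.loc[i, 'sample']!r}, "
            f"gene {context.loc[i, 'gene']!r}"
        )
    return ct


def read_ct_table(
    path: str | Path,
    format: str = "long",
    meta: str | Path | None = None,
) -> CtMatrix:
    """Read a Ct table from CSV/TSV and return a validated :class:`CtMatrix`.

    Parameters
    ----------
    path
        Input table; delimiter sniffed between comma and tab.
    format
        ``"long"`` (sample,gene,ct[,group,tissue,timepoint]) or ``"wide"``
        (gene column + one column per sample; requires ``meta``).
    meta
        Metadata sidecar (sample,group[,tissue,timepoint]); required for wide
        format, optional override for long format.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format not in {"long", "wide"}:
        raise InputError(f"unknown format {format!r}; expected 'long' or 'wide'")
    meta_df = None
    if meta is not None:
        meta_path = Path(meta)
        meta_df = pd.read_csv(meta_path, sep=_sniff_sep(meta_path), dtype=str)
        if "sample" not in meta_df.columns or "group" not in meta_df.columns:
            raise InputError("metadata sidecar needs columns sample,group[,tissue,timepoint]")
        if meta_df["sample"].duplicated().any():
            raise InputError("duplicate sample ids in metadata sidecar")
        meta_df = meta_df.set_index("sample")

    sep = _sniff_sep(path)
    if format == "long":
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        required = {"sample", "gene", "ct"}
        if not required.issubset(df.columns):
            raise InputError(f"long format needs columns {sorted(required)}, found {list(df.columns)}")
        if df.duplicated(subset=["sample", "gene"]).any():
            dup = df[df.duplicated(subset=["sample", "gene"])].iloc[0]
            raise InputError(f"duplicate (sample, gene) pair: ({dup['sample']!r}, {dup['gene']!r})")
        df = df.assign(ct=_parse_ct_column(df["ct"].replace("", np.nan), df))
        gene_order = list(dict.fromkeys(df["gene"]))
        sample_order = list(dict.fromkeys(df["sample"]))
        values = (
            df.pivot(index="gene", columns="sample", values="ct")
            .reindex(index=gene_order, columns=sample_order)
        )
        if meta_df is None:
            if "group" not in df.columns:
                raise InputError("long format without a 'group' column requires a metadata sidecar")
            meta_cols = ["group"] + [c for c in ("tissue", "timepoint") if c in df.columns]
            meta_df = df.drop_duplicates("sample").set_index("sample")[meta_cols]
            if (meta_df["group"] == "").any():
                bad = meta_df.index[meta_df["group"] == ""].tolist()
                raise InputError(f"missing group label for samples: {bad}")
            meta_df = meta_df.reindex(sample_order)
    else:
        values = pd.read_csv(path, sep=sep, index_col=0)
        values.index = values.index.astype(str)
        values.index.name = "gene"
        values.columns = values.columns.astype(str)
        if meta_df is None:
            raise InputError("wide format requires a metadata sidecar file")
    if meta_df is not None:
        missing = [s for s in values.columns if s not in meta_df.index]
        if missing:
            raise InputError(f"samples missing from metadata: {missing}")
        meta_df = meta_df.reindex(values.columns)
    return validate(CtMatrix(values, meta_df))


def write_ct_table(
    ct: CtMatrix,
    path: str | Path,
    format: str = "long",
    meta: str | Path | None = None,
) -> None:
    """Write a CtMatrix to CSV/TSV (extension picks the delimiter).

    In wide format the sample metadata goes to the ``meta`` sidecar path
    (defaults to ``<path>.meta.<ext>``).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    if format == "long":
        long = ct.values.reset_index(names="gene").melt(
            id_vars="gene", var_name="sample", value_name="ct"
        )
        long = long.merge(ct.meta, left_on="sample", right_index=True)
        long = long[["sample", "gene", "ct", "group", "tissue", "timepoint"]]
        # stable sample-major order matching first-appearance pivot on re-read
        long["sample"] = pd.Categorical(long["sample"], categories=ct.sample_ids, ordered=True)
        long["gene"] = pd.Categorical(long["gene"], categories=ct.genes, ordered=True)
        long = long.sort_values(["sample", "gene"], kind="stable")
        long.to_csv(path, sep=sep, index=False)
    elif format == "wide":
        ct.values.to_csv(path, sep=sep, index_label="gene")
        meta_path = Path(meta) if meta is not None else path.with_name(path.stem + ".meta" + path.suffix)
        ct.meta.to_csv(meta_path, sep=sep, index_label="sample")
    else:
        raise InputError(f"unknown format {format!r}")


def to_json(ct: CtMatrix) -> str:
    """Serialize the full dataset (values, metadata, roles) to a JSON string."""
    payload = {
        "genes": ct.genes,
        "samples": [vars(s) for s in ct.samples],
        "roles": {g: ct.roles[g] for g in ct.genes},
        "values": [[None if pd.isna(v) else float(v) for v in row] for row in ct.values.to_numpy()],
    }
    return json.dumps(payload, indent=2)


def from_json(text: str) -> CtMatrix:
    payload = json.loads(text)
    sample_ids = [s["sample_id"] for s in payload["samples"]]
    values = pd.DataFrame(
        [[np.nan if v is None else v for v in row] for row in payload["values"]],
        index=payload["genes"],
        columns=sample_ids,
        dtype=float,
    )
    meta = pd.DataFrame(
        {
            "group": [s["group"] for s in payload["samples"]],
            "tissue": [s.get("tissue", "") for s in payload["samples"]],
            "timepoint": [s.get("timepoint", "") for s in payload["samples"]],
        },
        index=sample_ids,
    )
    roles = pd.Series(payload.get("roles", {}), dtype=object).reindex(payload["genes"]).fillna(ROLE_REFERENCE)
    return CtMatrix(values, meta, roles)


def from_arrays(
    values: np.ndarray | Sequence[Sequence[float]],
    genes: Sequence[str],
    samples: Sequence[SampleMeta] | Sequence[Mapping[str, str]],
    roles: Mapping[str, str] | None = None,
) -> CtMatrix:
    """Convenience constructor from plain arrays and sample metadata records."""
    metas = [s if isinstance(s, SampleMeta) else SampleMeta(**s) for s in samples]
    meta = pd.DataFrame(
        {
            "group": [m.group for m in metas],
            "tissue": [m.tissue for m in metas],
            "timepoint": [m.timepoint for m in metas],
        },
        index=[m.sample_id for m in metas],
    )
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(genes), columns=meta.index)
    role_series = None
    if roles is not None:
        role_series = pd.Series(dict(roles), dtype=object)
    return CtMatrix(df, meta, role_series)
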
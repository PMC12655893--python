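"""Readers, writers, configuration and logging for the pipeline's tabular formats.

All on-disk formats are plain text with a mandatory header row, UTF-8, "."
decimal separator: comma-separated CSV throughout, except abundance tables
which are tab-separated because taxonomy lineage strings may contain commas.
Transients are stored long-format (sample_id,time_us,fluorescence) so that
instruments exporting different time grids per sample remain representable.

Floats written by :func:`write_tidy` use 17 significant digits, which makes
the write/read round trip exact for IEEE-754 doubles.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rhizojip")

#: printf-style format giving an exact decimal round trip for float64
FLOAT_FMT = "%.17g"

VARIETIES = ("T", "S")
SOILS = ("N", "A")
GROUPS = ("TN", "TA", "SN", "SA")

RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}


def setup_logging(level: int = logging.INFO) -> None:
    """Timestamped, leveled logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class FluorescenceTransient:
    """One dark-adapted fast fluorescence induction curve.

    Times are microseconds since flash onset; fluorescence in instrument
    arbitrary units. Times must be strictly increasing.
    """

    sample_id: str
    time_us: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.time_us = np.asarray(self.time_us, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_us.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence must have equal length")
        if np.any(np.diff(self.time_us) <= 0):
            raise ValueError(
                f"sample {self.sample_id!r}: times are not strictly increasing"
            )

    @property
    def time_ms(self) -> np.ndarray:
        return self.time_us / 1000.0

    def __len__(self) -> int:
        return self.time_us.size


class AbundanceTable:
    """Samples x taxa matrix of non-negative abundances.

    Columns are full taxonomy lineage strings of the form
    ``k__...;p__...;c__...;o__...;f__...;g__...;s__...``; rows are sample ids.
    Values are counts for raw tables, or non-negative reals after scaling.
    """

    def __init__(self, values: pd.DataFrame):
        values = values.astype(float)
        if (values.to_numpy() < 0).any():
            r, c = np.argwhere(values.to_numpy() < 0)[0]
            raise ValueError(
                f"negative abundance at sample {values.index[r]!r}, "
                f"taxon {values.columns[c]!r}"
            )
        if values.index.duplicated().any():
            raise ValueError("duplicate sample ids in abundance table")
        self.values = values

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)

    def row_sums(self) -> pd.Series:
        return self.values.sum(axis=1)

    def at_rank(self, rank: str) -> "AbundanceTable":
        """Aggregate taxa to a taxonomic rank by summing lineages sharing it."""
        names = [lineage_rank(t, rank) for t in self.taxa]
        if all(n is None for n in names):
            raise ValueError(f"rank {rank!r} absent from all lineages")
        keep = [i for i, n in enumerate(names) if n is not None]
        agg = self.values.iloc[:, keep].T.groupby(
            [names[i] for i in keep]
        ).sum().T
        return AbundanceTable(agg)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.values.loc[list(sample_ids)])


def lineage_rank(lineage: str, rank: str) -> str | None:
    """Extract the name at ``rank`` from a semicolon-delimited lineage.

    Returns None when the rank token is missing or empty.
    """
    try:
        prefix = RANK_PREFIXES[rank]
    except KeyError:
        raise ValueError(f"unknown rank {rank!r}") from None
    for part in lineage.split(";"):
        part = part.strip()
        if part.startswith(prefix):
            name = part[len(prefix):]
            return name if name else None
    return None


@dataclass
class TransientReadResult:
    transients: list[FluorescenceTransient]
    design: pd.DataFrame
    orphans_data_only: list[str] = field(default_factory=list)
    orphans_design_only: list[str] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{what}: missing required column {c!r}")


def read_design(path) -> pd.DataFrame:
    """Read the sample design table (sample_id, variety, soil).

    Adds the derived ``group`` column (variety + soil, e.g. ``TA``).
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["sample_id", "variety", "soil"], "design table")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in design: {dup!r}")
    bad_v = set(df["variety"]) - set(VARIETIES)
    if bad_v:
        raise ValueError(f"variety must be one of {VARIETIES}, got {sorted(bad_v)}")
    bad_s = set(df["soil"]) - set(SOILS)
    if bad_s:
        raise ValueError(f"soil must be one of {SOILS}, got {sorted(bad_s)}")
    df = df.copy()
    df["group"] = df["variety"] + df["soil"]
    return df


def read_transients(path, design_path) -> TransientReadResult:
    """Read long-format transients joined to the sample design.

    Samples with non-monotone time grids are rejected with a diagnostic;
    samples present in only one of the two files are reported as orphans.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "time_us", "fluorescence"], "transients")
    design = read_design(design_path)

    transients: list[FluorescenceTransient] = []
    rejected: list[str] = []
    for sid, grp in df.groupby("sample_id", sort=False):
        t = grp["time_us"].to_numpy(dtype=float)
        f = grp["fluorescence"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            logger.warning("sample %r rejected: non-monotone time column", sid)
            rejected.append(str(sid))
            continue
        transients.append(FluorescenceTransient(str(sid), t, f))

    data_ids = {tr.sample_id for tr in transients} | set(rejected)
    design_ids = set(design["sample_id"])
    orphans_data = sorted(data_ids - design_ids)
    orphans_design = sorted(design_ids - data_ids)
    for sid in orphans_data:
        logger.warning("sample %r present in transients but not in design", sid)
    for sid in orphans_design:
        logger.warning("sample %r present in design but has no transient", sid)
    return TransientReadResult(
        transients, design, orphans_data, orphans_design, rejected
    )


def read_abundance_table(path) -> AbundanceTable:
    """Read a taxa x samples TSV (first column: lineage) as samples x taxa.

    Duplicate lineages are summed with a warning; a negative cell is a hard
    error naming its coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    num = raw.apply(pd.to_numeric)
    neg = np.argwhere(num.to_numpy() < 0)
    if neg.size:
        r, c = neg[0]
        raise ValueError(
            f"negative abundance for taxon {num.index[r]!r} in sample "
            f"{num.columns[c]!r}"
        )
    if num.index.duplicated().any():
        dups = num.index[num.index.duplicated()].unique().tolist()
        logger.warning("duplicate taxa summed: %s", dups)
        num = num.groupby(level=0, sort=False).sum()
    return AbundanceTable(num.T)


def read_physiology(path) -> pd.DataFrame:
    """Read a long physiology table (sample_id, indicator, value)."""
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "indicator", "value"], "physiology")
    df = df.copy()
    df["value"] = pd.to_numeric(df["value"])
    return df


def read_soil(path) -> pd.DataFrame:
    """Read a soil chemistry table (soil_id, property, value, unit).

    Values like ``<0.02`` are detection-limit censored: stored with
    ``censored=True`` and the limit in ``bound``; ``value`` is NaN for them.
    """
    df = pd.read_csv(path, dtype={"value": str})
    _require_columns(df, ["soil_id", "property", "value", "unit"], "soil table")
    censored = df["value"].str.strip().str.startswith("<")
    bound = pd.to_numeric(df["value"].str.lstrip("< "), errors="coerce")
    value = bound.where(~censored)
    if (value.dropna() < 0).any():
        raise ValueError("soil property values must be non-negative")
    out = df.copy()
    out["value"] = value
    out["censored"] = censored
    out["bound"] = bound
    return out


# ---------------------------------------------------------------------------
# tidy writer / reader
# ---------------------------------------------------------------------------


def write_tidy(df: pd.DataFrame, path) -> None:
    """Write a long-format result table as CSV with exact float round trip."""
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_tidy(path) -> pd.DataFrame:
    # round_trip parser: exact inverse of the 17-significant-digit writer
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# configuration & integrity
# ---------------------------------------------------------------------------


def parse_config(path) -> dict:
    """Parse a flat ``key = value`` config file; ints/floats are coerced."""
    conf: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, _, val = line.partition("=")
            val = val.strip()
            for cast in (int, float):
                try:
                    val = cast(val)
                    break
                except ValueError:
                    continue
            conf[key.strip()] = val
    return conf


def check_samples_in_design(sample_ids, design: pd.DataFrame, context: str) -> None:
    """Refuse inputs whose sample ids are not a subset of the design's."""
    extra = set(map(str, sample_ids)) - set(design["sample_id"])
    if extra:
        raise ValueError(
            f"{context}: sample ids not present in design: {sorted(extra)}"
        )
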
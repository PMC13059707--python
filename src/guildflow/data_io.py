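"""Reading, writing and validation of the pipeline's tabular inputs.

Three tables drive the analysis:

* a **count table** of integer amplicon (ASV) read counts, stored on disk
  with features as rows and samples as columns (the QIIME convention) and
  held in memory as a samples x features :class:`pandas.DataFrame`;
* **sample metadata** with donor, treatment, time point (hours) and
  replicate for every sample;
* an optional **chemistry table** with pH and short-chain fatty acid
  (acetate, propionate, butyrate) concentrations in micromolar.

All readers validate aggressively: duplicate identifiers, negative counts,
unknown treatment levels and samples missing from the metadata are hard
errors, because silent misjoins are the classic failure mode of this kind
of pipeline.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "TREATMENTS",
    "METADATA_COLUMNS",
    "CHEM_COLUMNS",
    "SCFA_COLUMNS",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_chem",
    "write_chem",
    "validate_count_table",
    "validate_metadata",
    "validate_chem",
    "check_sample_join",
    "normalize_treatment",
]

#: Canonical treatment levels of the ex vivo fermentation design.
TREATMENTS = ("Control", "Oxygen", "Fiber", "OxygenFiber")

METADATA_COLUMNS = ("donor", "treatment", "time_h", "replicate")
SCFA_COLUMNS = ("acetate", "propionate", "butyrate")
CHEM_COLUMNS = ("pH",) + SCFA_COLUMNS

# case-insensitive aliases -> canonical treatment name
_TREATMENT_ALIASES = {
    "control": "Control",
    "ctrl": "Control",
    "oxygen": "Oxygen",
    "o2": "Oxygen",
    "fiber": "Fiber",
    "fibre": "Fiber",
    "oxygenfiber": "OxygenFiber",
    "oxygen+fiber": "OxygenFiber",
    "oxygen_fiber": "OxygenFiber",
    "oxygen fiber": "OxygenFiber",
    "o2+fiber": "OxygenFiber",
}


def normalize_treatment(label: str) -> str:
    """Map a free-form treatment label to its canonical level.

    Matching is case-insensitive and tolerant of ``+``/``_``/space
    separators (``"oxygen+fiber"`` -> ``"OxygenFiber"``).  Unknown labels
    raise ``ValueError``.
    """
    key = str(label).strip().lower()
    if key in _TREATMENT_ALIASES:
        return _TREATMENT_ALIASES[key]
    raise ValueError(
        f"unknown treatment level {label!r}; expected one of {sorted(set(_TREATMENT_ALIASES))}"
    )


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {dupes}")


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a samples x features count table and coerce it to int64.

    Raises ``ValueError`` on duplicate sample/feature ids, non-numeric
    entries or negative counts (naming the offending cell).
    """
    _check_unique(table.index, "sample")
    _check_unique(table.columns, "feature")
    try:
        numeric = table.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"count table contains non-numeric entries: {exc}") from exc
    if numeric.isna().any().any():
        raise ValueError("count table contains missing values")
    neg = numeric.lt(0)
    if neg.any().any():
        sample = neg.any(axis=1).idxmax()
        feature = neg.loc[sample].idxmax()
        raise ValueError(
            f"negative count at sample {sample!r}, feature {feature!r}: "
            f"{numeric.loc[sample, feature]}"
        )
    if ((numeric % 1) != 0).any().any():
        raise ValueError("count table contains non-integer values")
    out = numeric.astype("int64")
    out.index = pd.Index([str(i) for i in out.index], name=None)
    out.columns = pd.Index([str(c) for c in out.columns], name=None)
    return out


def read_count_table(
    path, format: str = "tsv", orientation: str = "features"
) -> pd.DataFrame:
    """Read a count table into a samples x features integer DataFrame.

    Parameters
    ----------
    path
        File to read.
    format
        ``"tsv"`` (default) or ``"biom"`` (BIOM 2.1 / HDF5).
    orientation
        For TSV only: ``"features"`` if features are rows on disk (the
        default, QIIME convention) or ``"samples"`` if samples are rows.
    """
    if format == "tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        if orientation == "features":
            raw = raw.T
        elif orientation != "samples":
            raise ValueError(f"orientation must be 'features' or 'samples', got {orientation!r}")
        return validate_count_table(raw)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unsupported count table format {format!r}")


def _read_biom(path) -> pd.DataFrame:
    """Read a BIOM 2.1 (HDF5) table: observations x samples CSR on disk."""
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["observation/ids"][:]]
        samp_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["sample/ids"][:]]
        data = fh["observation/matrix/data"][:]
        indices = fh["observation/matrix/indices"][:]
        indptr = fh["observation/matrix/indptr"][:]
    mat = sparse.csr_matrix((data, indices, indptr), shape=(len(obs_ids), len(samp_ids)))
    table = pd.DataFrame(mat.toarray(), index=obs_ids, columns=samp_ids).T
    return validate_count_table(table)


def write_count_table(table: pd.DataFrame, path) -> None:
    """Write a samples x features table as TSV with features as rows."""
    out = table.T.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a metadata table indexed by sample id."""
    _check_unique(meta.index, "sample")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {missing}")
    out = meta.copy()
    out.index = out.index.astype(str)
    out["treatment"] = [normalize_treatment(t) for t in out["treatment"]]
    out["donor"] = out["donor"].astype(str)
    out["time_h"] = out["time_h"].astype(float)
    out["replicate"] = out["replicate"].astype(int)
    return out


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (TSV, first column = sample id)."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    return validate_metadata(raw)


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def validate_chem(chem: pd.DataFrame) -> pd.DataFrame:
    """Validate a chemistry table (pH plus SCFA concentrations in uM)."""
    _check_unique(chem.index, "sample")
    missing = [c for c in CHEM_COLUMNS if c not in chem.columns]
    if missing:
        raise ValueError(f"chemistry table missing required column(s): {missing}")
    out = chem.copy()
    out.index = out.index.astype(str)
    out[list(CHEM_COLUMNS)] = out[list(CHEM_COLUMNS)].astype(float)
    bad_ph = out[(out["pH"] <= 0) | (out["pH"] >= 14)]
    if len(bad_ph):
        raise ValueError(f"pH outside (0, 14) for sample(s): {bad_ph.index.tolist()}")
    for col in SCFA_COLUMNS:
        if (out[col] < 0).any():
            bad = out.index[out[col] < 0].tolist()
            raise ValueError(f"negative {col} concentration for sample(s): {bad}")
    return out


def read_chem(path) -> pd.DataFrame:
    """Read the chemistry table (TSV, first column = sample id)."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    return validate_chem(raw)


def write_chem(chem: pd.DataFrame, path) -> None:
    out = chem.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def check_sample_join(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Require every count-table sample to have a metadata row."""
    missing = counts.index.difference(meta.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} sample(s) in the count table have no metadata row: "
            f"{missing.tolist()}"
        )
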
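"""Packaged machine-readable copies of the study's printed tables.

* ``table1`` -- cohort demographics per stratum (counts, age/BMI moments,
  group-comparison p-values as printed, ``<0.001`` kept as a string).
* ``table2`` -- per-stratum metabolite signatures: median out-of-bag AUC
  for each metabolite whose bootstrap AUC distribution passed the
  2.5%-quantile > 0.5 rule; blank cells mean "not selected".
* ``table3`` -- train/test AUC quantiles per model family and stratum
  with the printed differences and mean-absolute-difference columns.

These are verbatim transcriptions used for arithmetic-consistency checks
and set algebra; they are not inputs to any model fit.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_fixture"]

_TABLES = {"table1", "table2", "table3"}


class FixtureLookupError(KeyError):
    pass


def _path(name: str):
    return resources.files("metabosig") / "fixtures" / f"{name}.tsv"


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load one of the packaged printed tables as a DataFrame.

    ``table1`` is indexed by stratum key, ``table2`` by metabolite name
    (stratum keys as columns); ``table3`` has ``model`` and ``quantile``
    columns plus per-stratum train/test/diff columns.  Blank printed
    cells come back as NaN.
    """
    if table_id not in _TABLES:
        raise FixtureLookupError(f"unknown table_id {table_id!r}; one of {sorted(_TABLES)}")
    with resources.as_file(_path(table_id)) as p:
        if table_id == "table1":
            return pd.read_csv(p, sep="\t", index_col=0,
                               dtype={"p_sex": str, "p_age": str, "p_bmi": str})
        if table_id == "table2":
            return pd.read_csv(p, sep="\t", index_col=0)
        return pd.read_csv(p, sep="\t")
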
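"""Packaged reference data: the published 97-tumor BRCA1 carrier cohort.

Three small tables ship with the package:

* per-variant allelic-status counts for the full cohort (10 pathogenic,
  8 benign/likely-benign, 8 VUS variants; 90 breast + 7 ovarian tumors);
* the five family-1 tumors carrying c.4963T>C, with cellularity and VAF;
* the multifactorial classification inputs (prior and component likelihood
  ratios) for the two BRCT variants that reached a causality score.

Everything downstream (summaries, binomial evidence, posteriors) is
recomputable offline from these counts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_sample_table
from .types import BENIGN_GROUP, Tissue, VariantClass, VariantCohort

_COUNT_COLS = ["n_balance", "n_loss_variant", "n_loss_wt"]


def _data_path(name: str):
    return resources.files("lohclass.data").joinpath(name)


def load_cohort_counts() -> pd.DataFrame:
    """Per-variant (x tissue) counts of balance / loss-variant / loss-WT calls.

    Columns: variant_id, hgvs_p, effect, classification, tissue,
    n_balance, n_loss_variant, n_loss_wt, n_total.
    """
    with resources.as_file(_data_path("cohort_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    df["n_total"] = df[_COUNT_COLS].sum(axis=1)
    total = int(df["n_total"].sum())
    if total != 97 or df["variant_id"].nunique() != 26:
        raise AssertionError(f"packaged cohort corrupt: {total} samples")
    return df


def load_family1_samples() -> VariantCohort:
    """The five c.4963T>C tumors (VAFs 65/49/88/67/70%, cellularity 60-90%)."""
    with resources.as_file(_data_path("family1_tumors.tsv")) as p:
        return read_sample_table(p)


def load_classification_inputs() -> pd.DataFrame:
    """Priors and component LRs for c.4963T>C and c.5497G>A."""
    with resources.as_file(_data_path("classification_inputs.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def _subset(df: pd.DataFrame, classes, tissue: Tissue | None) -> pd.DataFrame:
    labels = {c.value for c in classes}
    out = df[df["classification"].isin(labels)]
    if tissue is not None:
        out = out[out["tissue"] == tissue.value]
    return out


def loss_wt_rate(
    df: pd.DataFrame, classes, tissue: Tissue | None = None
) -> tuple[int, int]:
    """(loss-of-WT count, total) over the given classes, optionally one tissue."""
    sub = _subset(df, classes, tissue)
    return int(sub["n_loss_wt"].sum()), int(sub["n_total"].sum())


def benign_loss_wt_rate(df: pd.DataFrame, tissue: Tissue | None = None) -> float:
    """Observed loss-of-WT rate among benign-group tumors (the binomial p for BV)."""
    k, n = loss_wt_rate(df, BENIGN_GROUP, tissue)
    return k / n


def pathogenic_loss_wt_rate(df: pd.DataFrame, tissue: Tissue | None = None) -> float:
    """Observed loss-of-WT rate among pathogenic tumors (the binomial p for PV)."""
    k, n = loss_wt_rate(df, {VariantClass.PATHOGENIC}, tissue)
    return k / n
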
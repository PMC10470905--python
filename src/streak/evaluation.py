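"""Benchmark harness: train/target splits, concordance, best-method shares.

The cross-validation scheme draws several independent seeded subsets at a
20-80 train/target split (a literal 5-way partition is impossible at those
fractions). Concordance between an estimate column and the receptor's
CLR-normalized ADT level is the Spearman rank correlation; the headline
statistic is the percentage of receptors for which each method attains the
highest average correlation, ties splitting the win equally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genesets import spearman_rho
from .pipeline import AbundanceEstimates, RunConfig, derive_seed, rna_baseline, streak_estimate, streak_train
from .preprocess import clr_normalize
from .types import CountMatrix, ValidationError

__all__ = ["SplitPlan", "make_splits", "concordance", "best_method_proportions",
           "sensitivity_sweep"]

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    repeat: int
    train_ids: list[str]
    target_ids: list[str]
    train_frac: float
    target_frac: float


def make_splits(cell_ids: list[str], n_repeats: int = 5, train_frac: float = 0.2,
                seed: int = 0) -> list[SplitPlan]:
    """Independent seeded draws of disjoint train/target cell subsets."""
    if not (0 < train_frac < 1):
        raise ValidationError("train_frac must be in (0, 1)")
    n = len(cell_ids)
    n_train = round(train_frac * n)
    if n_train < 1 or n - n_train < 1:
        raise ValidationError("split leaves an empty train or target part")
    ids = np.asarray(cell_ids)
    plans = []
    for rep in range(1, n_repeats + 1):
        rng = np.random.default_rng(derive_seed(seed, f"split:{rep}"))
        perm = rng.permutation(n)
        plans.append(SplitPlan(
            repeat=rep,
            train_ids=[str(c) for c in ids[perm[:n_train]]],
            target_ids=[str(c) for c in ids[perm[n_train:]]],
            train_frac=train_frac,
            target_frac=1.0 - train_frac,
        ))
    return plans


def concordance(estimates: AbundanceEstimates, adt_target: CountMatrix,
                method_label: str = "", rename_map: dict[str, str] | None = None,
                adt_raw: bool = False) -> pd.Series:
    """Per-receptor Spearman correlation with (CLR-normalized) target ADT.

    ``rename_map`` translates estimate column names to ADT feature ids where
    they differ. NaN marks receptors where either column is constant.
    """
    adt_vals = adt_target.values if adt_raw else clr_normalize(adt_target).values
    adt_pos = {f: i for i, f in enumerate(adt_target.feature_ids)}
    cell_pos = {c: i for i, c in enumerate(adt_target.cell_ids)}
    missing_cells = [c for c in estimates.cell_ids if c not in cell_pos]
    if missing_cells:
        raise ValidationError(f"estimate cells absent from ADT data: {missing_cells[:5]}")
    row_idx = [cell_pos[c] for c in estimates.cell_ids]
    rhos: dict[str, float] = {}
    for j, rec in enumerate(estimates.receptor_ids):
        adt_name = (rename_map or {}).get(rec, rec)
        if adt_name not in adt_pos:
            continue
        rhos[rec] = spearman_rho(estimates.values[:, j],
                                 adt_vals[row_idx, adt_pos[adt_name]])
    if not rhos:
        raise ValidationError("no estimate column matched an ADT feature")
    out = pd.Series(rhos, name=method_label or "rho")
    out.index.name = "receptor"
    return out


def best_method_proportions(table: pd.DataFrame) -> pd.Series:
    """Share (%) of receptors on which each method has the highest average rho.

    ``table`` rows are receptors (or receptor x repeat, averaged first via a
    MultiIndex level named ``receptor``), columns are methods. Ties split the
    win equally; all-NaN rows are dropped with a warning. Shares sum to 100.
    """
    if isinstance(table.index, pd.MultiIndex) and "receptor" in table.index.names:
        table = table.groupby(level="receptor").mean()
    wins = pd.Series(0.0, index=table.columns)
    n_rows = 0
    for rec, row in table.iterrows():
        if row.isna().all():
            logger.warning("receptor %s has no defined correlation for any method", rec)
            continue
        n_rows += 1
        best = row.max()
        tied = row.index[row == best]
        wins[tied] += 1.0 / len(tied)
    if n_rows == 0:
        raise ValidationError("no receptor with a defined correlation")
    return 100.0 * wins / n_rows


def sensitivity_sweep(rna: CountMatrix, adt: CountMatrix,
                      set_sizes: list[int] = (5, 10, 15, 20, 25, 30),
                      train_fracs: list[float] = (0.2,),
                      n_repeats: int = 1, seed: int = 0,
                      config: RunConfig | None = None,
                      receptor_to_gene: dict[str, str] | None = None) -> pd.DataFrame:
    """Grid of train+estimate+concordance runs over set sizes and split sizes.

    Returns a long-format frame (set_size, train_frac, repeat, receptor,
    method, rho). Failures at a grid point are recorded and the sweep
    continues.
    """
    base = config or RunConfig(seed=seed)
    rows = []
    for train_frac in train_fracs:
        plans = make_splits(rna.cell_ids, n_repeats=n_repeats,
                            train_frac=train_frac, seed=seed)
        for plan in plans:
            rna_tr = rna.subset_cells(plan.train_ids)
            adt_tr = adt.subset_cells(plan.train_ids)
            rna_tg = rna.subset_cells(plan.target_ids)
            adt_tg = adt.subset_cells(plan.target_ids)
            for set_size in set_sizes:
                cfg = RunConfig(**{**base.__dict__, "set_size": int(set_size)})
                try:
                    sets = streak_train(rna_tr, adt_tr, cfg)
                    est = streak_estimate(rna_tg, sets, cfg)
                    rho_streak = concordance(est, adt_tg, "streak")
                    r2g = receptor_to_gene or {r: r for r in est.receptor_ids}
                    mapping = {r: g for r, g in r2g.items()
                               if r in est.receptor_ids and g in rna.feature_ids}
                    rho_rna = (concordance(rna_baseline(rna_tg, mapping), adt_tg, "rna")
                               if mapping else pd.Series(dtype=float))
                except ValidationError as exc:
                    logger.warning("grid point (set_size=%s, repeat=%s) failed: %s",
                                   set_size, plan.repeat, exc)
                    continue
                for method, rho in (("streak", rho_streak), ("rna", rho_rna)):
                    for rec, value in rho.items():
                        rows.append({
                            "set_size": set_size, "train_frac": train_frac,
                            "repeat": plan.repeat, "receptor": rec,
                            "method": method, "rho": value,
                        })
    return pd.DataFrame(rows)
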
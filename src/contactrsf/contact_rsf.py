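"""Pair-level contact RSFs and the contact-vs-individual comparison.

Used points are contact locations; available points are the pair members'
non-contact interpolated fixes inside the dyad's home-range overlap,
capped at a 1:30 used:available ratio.  Pair models share the structure of
the top-selected individual model and aggregate to a population mean
weighted by contact counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.stats import pearsonr, spearmanr

from contactrsf.contacts import ContactEvent, PairRecord
from contactrsf.errors import DegenerateInputError, InvalidArgumentError
from contactrsf.landscape import EnvStack
from contactrsf.rsf import (
    PopulationRSF,
    RSFModel,
    UseAvailableDataset,
    aggregate_population,
    extract_covariates,
    fit_rsf,
    standardize,
)
from contactrsf.tracks import Trajectory

DEFAULT_RATIO_CAP = 30


def build_contact_dataset(
    pair_record: PairRecord,
    contacts: list[ContactEvent],
    itracks: dict[str, Trajectory],
    overlap_polygon: shapely.Geometry,
    env: EnvStack,
    ratio_cap: int = DEFAULT_RATIO_CAP,
    seed: int | None = None,
    layers=None,
) -> UseAvailableDataset:
    """Contact used/available design for one dyad.

    Available candidates pool both members' interpolated fixes inside the
    overlap polygon at non-contact timestamps within the pair's analysis
    window; when candidates exceed ``ratio_cap`` per used point a seeded
    uniform subsample of exactly that size is drawn.
    """
    if overlap_polygon.is_empty or overlap_polygon.area <= 0:
        raise DegenerateInputError("empty home-range overlap polygon")
    pair = pair_record.pair
    events = [e for e in contacts if e.pair == pair]
    start, end = pair_record.window
    events = [e for e in events if start <= e.timestamp <= end]
    if not events:
        raise DegenerateInputError("no contacts inside the pair window")
    contact_ns = {np.datetime64(e.timestamp, "ns").astype("int64") for e in events}

    rows_x, rows_y, rows_t = [], [], []
    for aid in pair:
        tr = itracks[aid].window(start, end)
        t_ns = tr.times.astype("int64")
        inside = shapely.contains_xy(overlap_polygon, tr.x, tr.y)
        non_contact = ~np.isin(t_ns, np.fromiter(contact_ns, dtype="int64"))
        keep = inside & non_contact
        rows_x.append(tr.x[keep])
        rows_y.append(tr.y[keep])
        rows_t.append(tr.times[keep])
    ax = np.concatenate(rows_x)
    ay = np.concatenate(rows_y)
    at = np.concatenate(rows_t)
    if len(ax) == 0:
        raise DegenerateInputError("no candidate available points in the overlap")

    n_used = len(events)
    cap = ratio_cap * n_used
    if len(ax) > cap:
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(len(ax), size=cap, replace=False))
        ax, ay, at = ax[pick], ay[pick], at[pick]

    ux = np.array([e.x for e in events])
    uy = np.array([e.y for e in events])
    ut = np.array([e.timestamp for e in events], dtype="datetime64[ns]")
    x = np.concatenate([ux, ax])
    y = np.concatenate([uy, ay])
    dates = np.concatenate([ut, at]).astype("datetime64[D]")
    label = np.concatenate([np.ones(n_used, dtype=int), np.zeros(len(ax), dtype=int)])
    cov = extract_covariates(x, y, dates, env, layers=layers)
    df = pd.DataFrame({"used": label, "x": x, "y": y, "date": dates})
    df = pd.concat([df.reset_index(drop=True), cov.reset_index(drop=True)], axis=1)
    covariates = list(cov.columns)
    df, standardizers = standardize(df, covariates)
    return UseAvailableDataset(
        owner=f"{pair[0]}-{pair[1]}",
        data=df,
        covariates=covariates,
        standardizers=standardizers,
        ratio=ratio_cap,
        seed=seed,
    )


def fit_contact_rsf(dataset: UseAvailableDataset, top_individual_formula) -> RSFModel:
    """Logistic contact vs non-contact fit with the top individual structure."""
    formula = list(top_individual_formula)
    if not formula:
        raise InvalidArgumentError("empty formula")
    return fit_rsf(dataset, formula)


def aggregate_contact_population(
    pair_models: list[RSFModel],
    pair_contact_counts: dict[str, float] | None = None,
) -> PopulationRSF:
    """Weighted mean across pairs; weights ∝ each pair's contact count."""
    sizes = pair_contact_counts or {m.owner: m.n_used for m in pair_models}
    return aggregate_population(pair_models, owner_pair_counts=None, owner_sample_sizes=sizes)


@dataclass
class ComparisonReport:
    """Coefficient- and surface-level contrast of contact vs individual RSF."""

    table: pd.DataFrame  # covariate, beta_contact, beta_individual, difference, ci, flag
    surface_spearman: float
    surface_pearson: float
    n_discordant: int

    def __post_init__(self):
        for r in (self.surface_spearman, self.surface_pearson):
            if math.isfinite(r) and not -1 <= r <= 1:
                raise InvalidArgumentError("correlation outside [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "surface_spearman": self.surface_spearman,
            "surface_pearson": self.surface_pearson,
            "n_discordant": self.n_discordant,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    def to_text(self) -> str:
        lines = [
            f"{'covariate':<18}{'b_contact':>11}{'b_indiv':>11}{'diff':>10}"
            f"{'ci_low':>10}{'ci_high':>10}  agree",
        ]
        for r in self.table.itertuples():
            lines.append(
                f"{r.covariate:<18}{r.beta_contact:>11.4f}{r.beta_individual:>11.4f}"
                f"{r.difference:>10.4f}{r.diff_ci_low:>10.4f}{r.diff_ci_high:>10.4f}"
                f"  {'yes' if r.sign_agreement else 'NO'}"
            )
        lines.append(
            f"surface correlation: spearman={self.surface_spearman:.4f} "
            f"pearson={self.surface_pearson:.4f}; {self.n_discordant} discordant covariates"
        )
        return "\n".join(lines)


def _sign_agreement(bc, lc, hc, bi, li, hi) -> bool:
    c_sig = lc > 0 or hc < 0
    i_sig = li > 0 or hi < 0
    if c_sig and i_sig:
        return (bc > 0) == (bi > 0)
    return c_sig == i_sig  # both null -> agree; one-sided significance -> discordant


def compare_rsf(
    pop_contact: PopulationRSF,
    pop_individual: PopulationRSF,
    env: EnvStack,
    date,
    standardizers: dict[str, tuple[float, float]],
) -> ComparisonReport:
    """Per-covariate differences (independent-SE joint CIs) plus Spearman /
    Pearson correlation of the two prediction surfaces over the grid."""
    if pop_contact.covariates != pop_individual.covariates:
        raise InvalidArgumentError("population models have mismatched covariates")
    from contactrsf.rsf import predict_surface

    diff = pop_contact.beta - pop_individual.beta
    se_d = np.sqrt(pop_contact.se**2 + pop_individual.se**2)
    rows = []
    for i, name in enumerate(pop_contact.covariates):
        rows.append(
            {
                "covariate": name,
                "beta_contact": float(pop_contact.beta[i]),
                "beta_individual": float(pop_individual.beta[i]),
                "difference": float(diff[i]),
                "diff_ci_low": float(diff[i] - 1.96 * se_d[i]),
                "diff_ci_high": float(diff[i] + 1.96 * se_d[i]),
                "sign_agreement": _sign_agreement(
                    pop_contact.beta[i],
                    pop_contact.ci_low[i],
                    pop_contact.ci_high[i],
                    pop_individual.beta[i],
                    pop_individual.ci_low[i],
                    pop_individual.ci_high[i],
                ),
            }
        )
    table = pd.DataFrame(rows)
    s_c = predict_surface(pop_contact, env, date, standardizers).ravel()
    s_i = predict_surface(pop_individual, env, date, standardizers).ravel()
    if np.ptp(s_c) == 0 or np.ptp(s_i) == 0:
        sp = pe = float("nan")
    else:
        sp = float(spearmanr(s_c, s_i).statistic)
        pe = float(pearsonr(s_c, s_i).statistic)
    return ComparisonReport(
        table=table,
        surface_spearman=sp,
        surface_pearson=pe,
        n_discordant=int((~table["sign_agreement"]).sum()),
    )
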
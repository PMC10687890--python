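"""Ground-truth scenario runners built on the synthetic simulator.

The dissociation scenario wires the full chain together: contacts are
steered onto food cells with a known odds multiplier while the animals'
general movement ignores food entirely, so the contact RSF should find a
positive food coefficient while the individual RSF stays null.
"""

from __future__ import annotations

import math

import numpy as np

from contactrsf import contact_rsf as crsf
from contactrsf import rsf
from contactrsf.contacts import classify_pair, detect_contacts, filter_pairs
from contactrsf.homerange import kde_homerange, overlap_region
from contactrsf.synthfix import gen_landscape, sim_population


def run_dissociation_replicate(
    seed: int,
    n_days: int = 56,
    extent_m: float = 4500.0,
    cell_m: float = 30.0,
    food_lattice_spacing: int = 3,
    n_pairs: int = 3,
    meetings_per_pair: int = 36,
    meeting_duration_min: float = 6.0,
    travel_lead_min: float = 20.0,
    steer_tau_min: float = 2.5,
    steer_sigma2: float = 0.25,
    flank_offset_m: float = 3.2,
    pair_center_gap_m: float = 600.0,
    sigma_m2: float = 350.0**2,
    tau_p_min: float = 20.0,
    food_odds: float = 3.0,
    formula=("food",),
    ratio: int = 30,
) -> dict:
    """One seeded replicate of the contact-vs-individual dissociation design.

    Movement is null with respect to food; meeting sites are drawn from the
    dyads' usage density with food odds multiplied by ``food_odds``.  Three
    design choices keep the generative truth cleanly dissociated: food
    sites sit on a regular lattice (a baiting-grid layout) so null usage
    correlates with food only at the areal rate; meetings are many and
    short so contact locations are near-independent draws; and most
    resource meetings place the two animals *flanking* the resource point
    (fixes in neighbouring cells, contact midpoint on the food cell), with
    just enough unflanked meetings that the animals' own food exposure
    stays at exactly the areal rate.  Returns the aggregated population
    coefficients for both models plus success flags (contact CI excludes
    zero and is positive; individual CI includes zero).
    """
    # food meetings land on food with probability p = odds*f/(1-f+odds*f);
    # flanking all but a fraction f/p of them keeps the animals' own
    # meeting fixes on food at exactly the areal rate f (null exposure)
    food_frac = 1.0 / food_lattice_spacing**2
    p_meet_food = food_odds * food_frac / (1.0 - food_frac + food_odds * food_frac)
    flank_prob = 1.0 - food_frac / p_meet_food

    n_cells = int(extent_m / cell_m) ** 2
    env = gen_landscape(
        extent_m,
        cell_m,
        n_days,
        n_food_sites=n_cells // food_lattice_spacing**2,
        seed=seed * 1009 + 7,
        food_persistence=1.0,
        food_layout="lattice",
        food_lattice_spacing=food_lattice_spacing,
    )
    # one animal per group; pair i joins groups 2i and 2i+1 side by side
    n_groups = 2 * n_pairs
    centers = []
    for p in range(n_pairs):
        cy = extent_m * (p + 1) / (n_pairs + 1)
        cx = extent_m / 2
        centers.append((cx - pair_center_gap_m / 2, cy))
        centers.append((cx + pair_center_gap_m / 2, cy))
    animal_ids = [f"A{i:02d}" for i in range(n_groups)]
    sexes = {aid: ("F" if i % 2 == 0 else "M") for i, aid in enumerate(animal_ids)}
    pairs = [(animal_ids[2 * p], animal_ids[2 * p + 1]) for p in range(n_pairs)]

    tracks, truth = sim_population(
        env,
        n_groups=n_groups,
        animals_per_group=1,
        tau_p_min=tau_p_min,
        sigma_m2=sigma_m2,
        fix_interval_min=5.0,
        n_days=n_days,
        attraction_coeffs={"food": math.log(food_odds)},
        seed=seed,
        gps_error_sd=0.0,
        dropout=0.0,
        meetings_per_day=meetings_per_pair * n_pairs / n_days,
        meeting_duration_min=meeting_duration_min,
        travel_lead_min=travel_lead_min,
        steer_tau_min=steer_tau_min,
        steer_sigma2=steer_sigma2,
        flank_offset_m=flank_offset_m,
        flank_prob=flank_prob,
        group_centers=centers,
        sexes=sexes,
        meeting_pairs=pairs,
        site_mode="density",
    )
    itracks = {t.animal_id: t for t in tracks}

    records = []
    pair_events: dict[tuple[str, str], list] = {}
    for a, b in pairs:
        events = detect_contacts(itracks[a], itracks[b], buffer_m=10.0)
        rec = classify_pair(itracks[a], itracks[b], sexes, env.grid)
        rec.n_contacts = len(events)
        records.append(rec)
        pair_events[rec.pair] = events
    kept = filter_pairs(records, min_contacts=10)

    hr = {
        aid: kde_homerange(
            np.column_stack([tr.x, tr.y]), env.grid, isopleth_levels=(0.50, 0.95), animal_id=aid
        )
        for aid, tr in itracks.items()
    }

    layers = list(formula)
    ind_models = []
    pair_models = []
    pair_counts: dict[str, float] = {}
    for rec in kept:
        a, b = rec.pair
        for aid in rec.pair:
            ds = rsf.build_individual_dataset(
                itracks[aid].window(*rec.window),
                hr[aid],
                env,
                ratio=ratio,
                seed=seed * 100 + animal_ids.index(aid),
                layers=layers,
                owner=aid,
            )
            ind_models.append(rsf.fit_rsf(ds, list(formula)))
        poly = overlap_region(hr[a], hr[b], 0.95)
        cds = crsf.build_contact_dataset(
            rec,
            pair_events[rec.pair],
            itracks,
            poly,
            env,
            ratio_cap=ratio,
            seed=seed * 100 + 51 + records.index(rec),
            layers=layers,
        )
        model = crsf.fit_contact_rsf(cds, list(formula))
        pair_models.append(model)
        pair_counts[model.owner] = rec.n_contacts

    pop_ind = rsf.aggregate_population(ind_models, owner_pair_counts={m.owner: 1.0 for m in ind_models})
    pop_con = crsf.aggregate_contact_population(pair_models, pair_counts)
    fi = list(formula).index("food")
    return {
        "n_pairs_kept": len(kept),
        "contacts_per_pair": [rec.n_contacts for rec in kept],
        "beta_food_contact": float(pop_con.beta[fi]),
        "ci_contact": (float(pop_con.ci_low[fi]), float(pop_con.ci_high[fi])),
        "beta_food_individual": float(pop_ind.beta[fi]),
        "ci_individual": (float(pop_ind.ci_low[fi]), float(pop_ind.ci_high[fi])),
        "contact_positive": bool(pop_con.ci_low[fi] > 0),
        "individual_null": bool(pop_ind.ci_low[fi] <= 0 <= pop_ind.ci_high[fi]),
        "pop_contact": pop_con,
        "pop_individual": pop_ind,
    }


def dissociation_study(base_seed: int, n_replicates: int = 20, **kwargs) -> dict:
    """Run seeded replicates and count dissociation successes."""
    results = []
    for i in range(n_replicates):
        results.append(run_dissociation_replicate(base_seed + i, **kwargs))
    n_ok = sum(1 for r in results if r["contact_positive"] and r["individual_null"])
    return {
        "n_replicates": n_replicates,
        "n_success": n_ok,
        "n_contact_positive": sum(r["contact_positive"] for r in results),
        "n_individual_null": sum(r["individual_null"] for r in results),
        "replicates": results,
    }
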
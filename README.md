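# contactrsf

Resource selection functions for animal **contact** locations.

`contactrsf` detects direct contacts between GPS-tracked animals from
continuous-time movement-model interpolations, models the landscape
drivers of those contact locations with a used-available logistic design
(the *contact RSF*), and compares the aggregated population-level contact
RSF against the aggregated individual-level RSF of the same animal pairs.

The workflow:

1. **Movement models** (`contactrsf.ctmm`) — fit IID / OU / integrated-OU /
   OU-foraging Gaussian movement models per animal with exact Kalman-filter
   likelihoods, select by AIC, and interpolate each track onto a regular
   5-minute grid with a Kalman smoother.
2. **Contacts** (`contactrsf.contacts`) — direct contact = co-location of a
   dyad at the same grid timestamp within a 10 m buffer.  Female-female
   dyads are classified within/between/temporarily-same-group from weekly
   kernel-density core-area overlap (0.5 threshold); male-involved dyads are
   between-group by definition.  Pairs need more than 10 contacts to enter
   the analyses.
3. **Home ranges** (`contactrsf.homerange`) — kernel-density utilization
   distributions with mass-ranked isopleths (95% availability, 50% core)
   and dyadic overlap regions.
4. **Individual RSF** (`contactrsf.rsf`) — used = interpolated fixes,
   available = 30 uniform points per used point inside the 95% home range;
   collinearity screen at |r| >= 0.6; per-individual logistic fits; model
   structure selected by cumulative-log-likelihood AIC across individuals;
   two-stage weighted population aggregation; fivefold cross-validation
   with area-adjusted-frequency Spearman validation.
5. **Contact RSF** (`contactrsf.contact_rsf`) — used = contact locations,
   available = the pair's non-contact fixes inside the home-range overlap
   (capped at 1:30); same model structure as the top individual model;
   pair-level aggregation weighted by contact counts; coefficient- and
   surface-level comparison of the two population models.
6. **Synthetic data** (`contactrsf.synthfix`) — landscapes with known
   covariate semantics and socially structured OU movement with steered
   between-group meetings, providing ground truth for every stage.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (detector oracle
equivalence, movement-model correctness, isopleth calibration, RSF
recovery, the contact-vs-individual dissociation study, end-to-end
determinism, and the printed method constants).  The dissociation study
runs 20 seeded replicates and takes a few minutes.

## CLI

The pipeline runs end to end from a YAML config (every parameter has the
method default: 5-min interval, 10 m buffer, 1:30 ratio, 95%/50%
isopleths, 0.6 / 0.5 / 10 thresholds, fivefold CV):

```bash
contactrsf run --out-dir out --seed 7            # all 11 stages
contactrsf simulate --out-dir out --seed 7       # or stage by stage
contactrsf fit-ctmm --out-dir out --seed 7
contactrsf interpolate ... detect-contacts ... classify-pairs ...
contactrsf filter-pairs ... fit-individual-rsf ... select-model ...
contactrsf fit-contact-rsf ... aggregate ... compare
contactrsf predict --out-dir out --population contact --date 2020-01-02
```

Stages write plain-text artifacts (CSV tracks and datasets, JSON models
and manifests, ESRI ASCII-grid rasters) into the output directory, plus a
`manifest.json` with a sha256 per artifact; reruns with the same seed are
byte-identical.  With no input tracks the `simulate` stage generates a
synthetic population; external data plug in via `tracks_csv` /
`env_manifest` config keys (tracks CSV: `animal_id, timestamp, x, y`
with UTC ISO-8601 timestamps and projected coordinates in meters).

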
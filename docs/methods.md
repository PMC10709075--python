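# Methods

## The model

`pancreg` implements a cohort-level decision model of regionalizing
pancreatic cancer surgery to high-volume centers (HVCs, ≥20 resections
per year).  It is a single 30-day decision cycle with absorbing
outcomes, evaluated in closed form — no multi-cycle transitions,
discounting or half-cycle correction.  For an annual statewide cohort:

1. **Funnel.** Incident cases `I` are reduced to the operated cohort:
   `N_resectable = I · p_resectable`, `N = N_resectable · p_resection`.
2. **Allocation.** Operations split between center classes:
   `N_hvc = N · f`, `N_lvc = N − N_hvc`, where `f` is the HVC fraction
   of the policy being evaluated (0.466 in the current state, 1.0 under
   complete regionalization, intermediate for partial regionalization).
3. **Outcomes.** Each class contributes marginal 30-day counts,
   `deaths_k = N_k · d_k` and `complications_k = N_k · c_k`, and a cost
   `complications_k · u_k` where `u_k` is the per-complication unit
   cost.  The cost of the index resection is assumed equal across
   classes, so complication management is the only cost differential.
4. **Differential.** The headline output is current-minus-future totals
   for deaths, complications and cost; positive values are savings from
   regionalization.

Deaths and complications are independent marginal counts: whether a
patient can both die and have a complication is not modelled, and the
published outputs this package reproduces report marginals only.

## Rounding

Two policies, chosen per call:

* `half-up` (default): expected counts are rounded half-away-from-zero
  to whole patients at every funnel/allocation/outcome step.  This is
  the reporting convention — published cohort tables print integer
  patients — and it reproduces every cell of the reference output table
  exactly.  The LVC allocation is computed as a remainder
  (`N − round(N·f)`), never rounded independently, so patients are
  conserved by construction.
* `off`: fractional expected counts are carried through every step,
  with costs computed on fractional complication counts.  Sweeps,
  threshold solving and PSA use this mode internally: the differential
  is then linear in the HVC fraction and multilinear in the parameters,
  giving smooth, strictly monotone curves instead of rounding
  staircases.

Under `half-up`, pooling effects of rounding can shift a total by ±1
per center class (e.g. with identical rates at both classes, splitting
977 patients 522/455 gives 9+8 = 17 expected deaths at 1.8 % versus 18
pooled).  Invariants that are exact in `off` mode (zero differential
when rates and costs are equal; monotonicity in `f`) therefore hold
only to ±1 per center under `half-up`; the tests encode both forms.

Currency is exact: unit costs are whole dollars, and in `half-up` mode
every cost is the exact integer product of a complication count and a
unit cost.

## Parameters

Stored as fractions in [0, 1] (percent values divided by 100 on entry);
the LVC fraction is always derived as `1 − p_hvc`.

| field | default | range | units / meaning |
|---|---|---|---|
| `annual_incidence` | 5958 | — | incident cases per year (statewide projection) |
| `p_resectable` | 0.41 | — | localized/regional at diagnosis |
| `p_resection` | 0.40 | 0.21–0.41 | resectable patients operated |
| `p_hvc` | 0.466 | — | current HVC share of operations |
| `hvc_mortality_30d` | 0.018 | 0.017–0.021 | 30-day mortality, HVC |
| `lvc_mortality_30d` | 0.052 | 0.045–0.061 | 30-day mortality, LVC |
| `hvc_complication_30d` | 0.343 | 0.337–0.343 | 30-day complications, HVC |
| `lvc_complication_30d` | 0.398 | 0.398–0.413 | 30-day complications, LVC |
| `cost_per_complication_hvc` | 16815 | 9101–17947 | USD per complication |
| `cost_per_complication_lvc` | 16815 | 9101–17947 | USD per complication |

Parameters without a listed range have a single published source and
get a degenerate range (`low == high`).  The default mortality rates
are the midpoints of the published per-class ranges; both unit costs
equal the published mean complication cost and are kept as separate
fields so the differential-cost scenario needs no structural change.
The published resection-rate range appears in two forms in the source
literature (21–41 % in the evidence table, 27–41 % in prose); the
tabulated 21–41 % is used and the discrepancy is simply noted.

## Scenarios

* **baseline** — current allocation (46.6 % HVC) vs complete
  regionalization: 17 fewer deaths, 29 fewer complications, $487,635
  saved (half-up).
* **partial_regionalization(f=0.75)** — future state reaches only 75 %
  HVC: 9 fewer deaths.
* **differential_complication_cost** — LVC complications cost $22,364,
  HVC $11,098.  The published dollar values are taken literally even
  though they are not an exact 2:1 ratio (2 × 11,098 = 22,196): printed
  values outrank the word "double".
* **widened_complication_gap** — complication rates widened to 31.5 %
  (HVC) / 43 % (LVC).  The widened rates redefine complication risk
  globally, i.e. in *both* states; the alternative reading (current
  state keeps baseline rates) contradicts the "gap between classes"
  framing.

Every scenario result carries both rounded and unrounded differentials
side by side, because the reported sensitivity figures cannot all be
reproduced under any single rounding convention (next section).

### Known discrepancies

Three reported sensitivity figures do not follow from their stated
inputs under either rounding policy.  `discrepancy_report()` recomputes
them; the package asserts they are *not* reproduced and emits its own
values instead:

| scenario | reported | recomputed half-up | recomputed unrounded |
|---|---|---|---|
| partial (75 %), cost saved | $256,870 | $269,040 | $256,639 |
| widened gap, complications averted | 58 | 59 | 60.0 |
| widened gap, cost saved | $974,295 | $992,085 | $1,008,975 |
| differential cost, cost saved | $2,659,211 | $2,665,170 | $2,658,071 |

(The reported "15 fewer complications" for the partial scenario does
match the unrounded value 15.26 rounded to a whole patient, and the
reported 58 with the reported $974,295 are mutually inconsistent at the
$16,815 unit cost: 58 × 16,815 = $975,270.)  These rows are documented
inconsistencies, not calibration targets.

## Sensitivity tools

* **One-way sweeps** evaluate the current-vs-full-regionalization
  differential at `n_points` evenly spaced values across a parameter's
  literature range, all else at baseline, in `off` mode.  `tornado()`
  summarizes each non-degenerate parameter by the differential at its
  two endpoints, sorted by span.
* **Threshold solving** finds the smallest future HVC fraction in
  `[p_hvc, 1]` whose differential reaches a target, by bisection to
  1e-6.  In `off` mode the differential is linear in the fraction, so
  bisection is exact up to tolerance; `None` means the target is
  unattainable even at complete regionalization.
* **PSA** samples parameter sets within their ranges (see below),
  evaluates the differential per draw in `off` mode, and reports means,
  central 95 % intervals, and the fraction of draws with positive cost
  savings.  Identical seeds give bit-identical summaries.

## Parameter sampling

The literature gives point estimates and ranges, not distributions.
The generator's defaults are those published ranges; they are the study
conditions, not knobs.

* `uniform` (default): uniform on [low, high] — the least-assumptive
  reading of a literature range.
* `beta` (proportions) / `gamma` (costs): method-of-moments fits with
  mean at the selected value and the range read as an approximate
  central 95 % interval (`sd = width / 3.92`), then truncated to
  [low, high] by rejection.  Truncation keeps every draw inside its
  published bounds — an invariant the rest of the package relies on —
  and handles ranges whose selected value sits on an endpoint (e.g. the
  HVC complication rate, 0.343 at the top of 0.337–0.343), where no
  untruncated unimodal fit could place 95 % mass inside the range.
  The beta concentration is floored at 2 to keep densities unimodal.
* `point`: the selected value, repeated (used automatically for
  degenerate ranges).

Parameters are sampled independently; in particular the HVC and LVC
unit costs are drawn independently over the same $9,101–$17,947 range.
This is a real limitation: no joint information is published, but
independent cost draws mean roughly a quarter of PSA draws price HVC
complications above LVC ones, which is why the PSA's
fraction-cost-saving is ≈0.73 rather than ≈1 even though the clinical
differentials are almost surely positive under these ranges.

Seeding: each parameter draws from a substream derived from the root
seed and the parameter's own name, so adding or removing one parameter
from a spec does not perturb the draws of the others, and fixtures are
stable across package versions.  Fixture CSVs are written with full
`repr` precision plus a sidecar recording the spec, sufficient to
regenerate the CSV byte-identically.

### What the generator does and does not emulate

It emulates between-study heterogeneity of the published inputs —
parameter sets that any of the cited sources could plausibly have
produced.  It does not generate patient-level data, correlated
parameters, time trends, or center-level heterogeneity within a volume
class.  Passing tests therefore demonstrate correctness of the
arithmetic and stability under literature-plausible inputs, not
validity of the underlying volume-outcome estimates themselves.

## Numerical and design notes

* Rounding is half-away-from-zero (`floor(x + 0.5)` for x ≥ 0), not
  Python's banker's rounding, chosen because it reproduces every
  published integer count.
* Problem sizes: the model itself is closed-form (sub-millisecond); the
  default PSA in the acceptance script uses 2,000 draws, and test-suite
  Monte-Carlo checks use 300–5,000 draws, sizes at which the
  law-of-large-numbers assertions have comfortable margins.
* Degenerate inputs: an empty cohort yields all-zero states; a
  degenerate range yields a constant sweep; a scenario whose future
  fraction equals the current one yields a zero differential.
* Validation reports *every* violated field at once rather than
  failing on the first, since config files are the main entry point.

## Limitations

* Single 30-day cycle: no 90-day outcomes, readmissions, long-term
  survival or quality-adjusted life years; with no effectiveness
  denominator there is no ICER machinery.
* Marginal counts: death/complication overlap is not modelled.
* The provenance of the unit cost (cost-to-charge ratios, wage indices,
  inflation adjustment) is upstream of this model; the cost is taken as
  a given input.
* Independent parameter sampling (above) likely overstates cost
  uncertainty in the PSA.
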
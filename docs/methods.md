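# Methods

## The model

`carelex` implements a symbolic-dynamics reading of clinical practice.
At every decision point a dyad is formed from two discrete codes:

* a **derangement symbol** — for each goal variable, whether the value
  lies below, within, or above its goal range (codes 0/1/2). The
  mechanical-ventilation (MV) scheme uses four variables: SpO2
  (goal > 90 %), pH (lower bound < pH < 7.45, lower bound
  disease-specific, default 7.30, overridable per patient), mean
  arterial pressure (> 65 mmHg) and plateau pressure (< 30 cmH2O). The
  dialysis (HD) scheme uses six elements: hemoglobin vs 10–12 g/dL,
  ferritin vs 200–500 ng/mL, transferrin saturation vs 20 %, ESA-dose
  tertile (none/T1/T2/T3, tertiles over all positive doses in the
  dataset), month-over-month hemoglobin trend (stable = |Δ| ≤ 0.5
  g/dL/month, configurable) and distance of hemoglobin from the target
  band (in-range / ≤1 / ≤2 / >2 g/dL outside).
* an **intervention symbol** — direction only (−1/0/+1) for each of the
  active ventilation mode's settings (VC: tidal volume, flow, pause,
  FiO2, PEEP, rate; PC: inspiratory pressure, inspiratory time, FiO2,
  PEEP, rate) plus a fluid-bolus flag, with mode switches as their own
  two symbols; or, for dialysis, the ESA action (start, stop, ±25–50 %,
  ±>50 % by dose ratio; sub-25 % changes code as no action, since the
  category system leaves them unassigned) and the iron action (start,
  stop, intensify).

Goal inequalities are honored exactly as stated, strictly: SpO2 = 90
codes *below*, Pplat = 30 codes *within*, TSAT = 20 codes *below*. A
uniform ternary state code is used for all variables; one-sided goals
simply never emit their unbounded side.

Concatenating the two symbols gives a canonical **word**
(`MV|D0212|VC:000+0-|B0`, `HD|D121010|E0|I0`); the grammar is injective
and machine-parseable, and round-trips exhaustively over both schemes'
alphabets. Word counting, rank-frequency tabulation (ordinal ranks,
ties broken lexicographically for determinism) and OLS fitting of
`ln f` on `ln r` (natural logs; slope estimates −a, intercept ln β,
squared Pearson r reported as R²) follow.

## Null models

The intermittent-silence typist strikes one of `N` non-space keys
uniformly, or the space (probability `q`) which terminates the word.
Word lengths are geometric, `P(L) = q(1−q)^L` for `L ≥ 0`; analyses
condition on `L ≥ 1` (an empty word — two consecutive spaces — is not a
word) and renormalize. All `N^L` words of length `L` are equiprobable
with probability `q((1−q)/N)^L`, so the rank-frequency curve is a
staircase whose large-rank log-log slope is `ln(1−q)/ln N − 1`; the
random-text variant fixes `q = 1/(N+1)`, giving `−ln(N+1)/ln N`. These
closed forms are derived from the verbal definition of the process
(uniform independent keystrokes, space terminates); block tables store
exact integer rank boundaries and are never expanded word-by-word, so
`N = 1946` poses no memory problem. Block-table fits place one point
per block at the geometric-mean rank; the fit converges monotonically
to the closed form as the maximum tabulated length grows (verified for
N ∈ {2, 5, 13}) and agrees within 5 % at 20–40 blocks for all alphabet
sizes used.

The conceptual keyboards: volume-controlled ventilation has 12
setting-change keys (up/down per setting), one bolus key and one space
bar (14 keys); pressure-controlled has 10 + 1 + 1 = 12. The discrete
intervention alphabet counts each setting direction in {down, none, up}
and the bolus flag, including the all-unchanged/no-bolus pattern:
2·3⁶ = 1458 (VC) + 2·3⁵ = 486 (PC) + 2 mode switches = 1946. Inclusion
of the null pattern is what makes the closed form reproduce these
counts exactly.

Word length on the clinical side is the **number of inputs changed**
(settings plus bolus; a mode switch counts as one changed input), not
keystrokes — capped at 7 (VC) and 6 (PC). The typist simulator supports
both metrics; the distinct-inputs metric maps keystrokes through the
keyboard's key→input map. The effective space frequency is estimated as
completions / (interventions + completions) — the share of "space"
events in the concatenated keystroke stream. Mode switches are excluded
from per-mode length tables (they belong to neither keyboard).

## Synthetic data

The generators supply inputs with the statistical structure the
analysis assumes, at the study's scale: 29 subjects each managing 100
virtual ventilation patients (analyses often use the last 25 per
subject), and ~30 dialysis patients followed monthly for 3 years.

The ventilation generator draws each step's (derangement, intervention)
word from a population-wide Zipf(a) usage law, default a = 0.95. A
single global ranked word list carries probability ∝ rank^−a; global
ranks are dealt (largest-remainder, capacity-aware) across derangement-
state × mode cells with weights `(w_d v_m)^{1/a}`, which makes each
cell's mass proportional to `w_d v_m` and each cell's conditional law
Zipf(a) over that cell's own preference ordering. Orderings are seeded
permutations of the mode's full intervention alphabet, shared by all
subjects — the idealization that the population's habitual responses
are common conventions, which is what lets population-level power-law
behavior mirror individual behavior. Patients complete with probability
0.2 after each intervention (geometric solution lengths, mean 4;
q̂ ≈ 0.2 by construction) and are abandoned after 60 steps (probability
≈ 1.4·10⁻⁵ at the default completion rate). Physiologic values realize
the drawn derangement state from a fixed repertoire of eight recurring
states with a heavy-tailed mix; settings move by fixed per-setting step
sizes so the encoder recovers exactly the drawn direction pattern.

The dialysis generator evolves hemoglobin as a mean-reverting response
to ESA dose (setpoint 10 + 1.2·ln(1 + dose/5000) g/dL, monthly noise SD
0.5 g/dL) with a concentrated stochastic prescriber policy whose ESA
moves land exactly in the coding bins (×1.3, ×1.75, ×0.65, ×0.4,
start/stop) and whose iron moves react to TSAT and ferritin.

What the generators do **not** emulate: ventilator physiology (settings
do not feed back on the derangement state), erythropoiesis
pharmacokinetics beyond the one-parameter response, practitioner
learning or heterogeneity of style, and charting artifacts. Passing
tests therefore demonstrate that the pipeline measures faithfully what
the encoding defines — not that real practice has these statistics.

## Numerical and analysis conventions

* **Fit truncation.** Finite samples flatten the low-count tail of an
  empirical rank-frequency table, so fits expose `min_count`. The
  conventions used in the package's own analyses: population-scale
  tables (~3·10³–10⁵ tokens) are fitted with `min_count = 5`; small
  per-group tables with `min_count = 2`; single-cell conditional checks
  with `min_count = 3` (balancing tail flattening against the slight
  head distortion the integer dealing of global ranks introduces).
  Defaults fit all ranks.
* **Degenerate tables** (all frequencies equal) return slope 0 with an
  explicit flag rather than an error; groups that cannot be fitted are
  excluded and listed.
* **Ranks and ties.** Ordinal ranks 1..N; ties broken by lexicographic
  word order so identical inputs give byte-identical tables. Length
  tables rank length *values* by frequency, smaller length first on
  ties.
* **Observed-vs-null comparisons** renormalize the null length law over
  the shared support 1..max(observed length), so both share vectors sum
  to 1; divergence is summarized by total-variation distance and the
  maximum absolute log-share difference, alongside the observed table's
  fitted slope vs the null block-table slope.
* **Incomplete dyads** (rows missing a physiologic value or a
  mode-required setting) are dropped at encoding time with the count
  reported; clean + excluded always equals the input size. Dialysis
  month gaps are allowed; trends compare against the immediately
  preceding available month, and a patient's first month codes its
  trend as stable.
* **Seeds.** Every generator is a pure function of (config, seed); no
  global random state. The acceptance script derives all sub-seeds from
  its single `--seed`.
* **Problem sizes.** The acceptance computations use 29 subjects × 25
  patients for population recovery (~3000 dyads), 29 subjects × 100
  patients for per-subject summaries, 10⁵ words for Monte-Carlo/analytic
  agreement, and 20–40 blocks for block-table fits — sizes at which the
  estimators' sampling spread is well inside the tolerances asserted.

## Known limitations

* OLS on log-log axes is the estimator of record here; it is biased on
  heavy-tailed samples and no maximum-likelihood (Clauset-style)
  alternative is provided.
* The per-subject streams of a 25-patient session (~100 words) are too
  short for tight exponent recovery; per-subject recovery is therefore
  demonstrated on subjects sampling their Zipf sources directly, and
  full-scale (100-patient) per-subject fits are reported as summaries
  rather than recovery checks.
* The word grammar treats intervention magnitude as irrelevant by
  design; analyses that need magnitude must re-encode.
* The dialysis scheme cannot attribute words to individual prescribers
  (records are per patient-month), so per-provider fits are only
  available for the ventilation scheme.
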
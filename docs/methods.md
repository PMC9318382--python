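# Methods

## Problem and approach

Donkey-hide gelatin (Ejiao) commands a premium that makes substitution
with cattle-, pig-, and horse-hide gelatin common. Peptide markers
selected from protein databases are unreliable for this product: donkey
and horse share their *Equus* database entries, so "donkey-specific"
database peptides — including the pharmacopoeia markers — also occur in
horse gelatin. gelmark implements the database-independent alternative:
compare the tryptic-peptide MS1 ion inventories of authentic gelatins
from each species directly and keep as markers only the ions present in
every batch of one species and absent from all others. Selected markers
are then quantified by triple-quadrupole MRM against per-marker
calibration lines, and samples are authenticated from the resulting
percent contents.

## Ion inventories (feature detection)

Centroided MS1 peaks (m/z 100–1200, inclusive) are chained into isotope
envelopes: peaks co-eluting within 0.05 min whose successive m/z gaps
share a common value up to 1.2 Th within 0.02 Th. The charge is read
off the spacing — a z-charged peptide's isotopologues are 1.00335/z Th
apart — accepting z = round(1/spacing) for z in 1..6 when the observed
spacing matches 1.00335/z within 0.01 Th. The monoisotopic peak is
taken as the lowest-m/z peak of the envelope (tryptic peptides under
~2.5 kDa have dominant or near-dominant monoisotopic peaks), the
feature intensity as the envelope apex. The inventory keeps features
with z in {2, 3, 4} (multiply charged ions are peptides; singly charged
ions are treated as matrix contaminants) and apex intensity ≥ 1e4
counts, the detection criterion used throughout. Neutral masses use
m_proton = 1.007276 Da. The linking tolerances are not printed in the
source study; they are set well inside its 0.1 Da screening accuracy
and exposed in `constants.py` and as function parameters.

## Cross-species screening

Candidate ions (the union of all sample inventories, single-linkage
clustered at 0.1 Th / 0.5 min across runs) are looked up in every
sample the way an EIC is read at 0.1 Da mass accuracy: the *closest*
feature in m/z (ties by RT) within the window is the candidate's signal,
and the candidate is detected only if that signal reaches 1e4 counts.
Deciding on the closest peak rather than "any peak in the window"
matters: a weak candidate a few hundredths of a Th away from an intense
unrelated ion must not inherit that ion's detection, which is exactly
the situation among the closely spaced reported literature markers
(e.g. m/z 765.8 vs 765.8556).

Classification is set-theoretic per candidate: detected in ≥1 batch of
every species → shared by all; in several species → shared subset; in a
single species in all of its batches (consistency 1.0, configurable) →
species-specific; in a single species but not all batches → rejected
for low consistency. Charge-state and first-isotope variants (neutral
masses differing by k·1.00335 Da, k ∈ {0, 1}, within 0.05 Da at the
same RT within 0.1 min) are merged union-find style, keeping the
highest-intensity member, before panel ids (DM1…, HM1, CM1…, PM1…,
numbered by ascending m/z per species) are assigned. The k-offset rule
deliberately never merges co-eluting peptides whose masses differ by
anything else — four donkey markers share RT 23.36 min yet remain
distinct. Cross-run RT matching uses 0.5 min (looser than within-run
linking, since screening crosses injections); literature markers print
no RT, so their re-evaluation matches on m/z and intensity only.

## Quantification

Calibration is unweighted OLS of standard amount (mg) on MRM peak area,
as published (y = ax + b with R², no weighting stated). LOD and LOQ are
the smallest tested amounts whose signal-to-noise exceeds 3 and 10;
S/N values are inputs here, not computed from chromatograms. Content is
100·((area − intercept)/slope)/sample_mass with a 5 mg digest mass;
negative estimates clamp to 0 and are flagged absent.

The pharmacopoeia donkey marker (CP) cross-reacts with horse gelatin.
Its horse-corrected content is max(0, cp − r·hm1) on the content scale,
with r the median CP/HM1 ratio over pure-horse references. A scalar r
is the simplest model consistent with most of the published survey's
indirect values (r ≈ 0.504 fitted on one donkey+horse sample transfers
to its sibling within 0.15); it does not reproduce every row — the
published comparison itself shows the ratio differs between samples —
so r is exposed as data (`estimate_horse_ratio`), never hard-coded.

## Authentication

A species is present when its specific marker's content exceeds 5%
("not more than 5%" reads as not detected; the boundary itself is
absent). The verdict uses DM4 alone for donkey — CP contents are
carried for reporting but never drive the call. A sample is authentic
iff donkey is the only species present. Fake samples are categorised by
their adulterant combination ({cattle}, {horse}, {pig, horse},
{cattle, horse}; anything else is other_mixture), with one refinement:
a horse-only adulterant set splits into `horse` vs `donkey_horse`
according to donkey co-presence, mirroring how the surveyed products
were reported. Raising the threshold can only remove species calls, so
it can never turn an authentic sample fake through a non-donkey marker.

## Synthetic data

The generator emulates the study design: four species with 4/3/4/4
batches (reference + homemade hides), 3-peak isotope envelopes at
1.00335/z spacing with geometric intensity decay (ratio 0.6), neutral
masses uniform in 800–3400 Da, charges 2+/3+/4+ weighted
0.45/0.40/0.15, RTs uniform over a 1–29 min gradient, log-normal
intensities (log10 mean 5.0, sd 0.5) floored at 1.5e4 for planted ions,
per-sample m/z jitter ≤ 0.02 Th and RT jitter ≤ 0.1 min, 50 singly
charged contaminant envelopes and 200 sub-threshold noise peaks (log10
mean 3.0, sd 0.4, capped at 9.5e3) per sample.

The full-scale preset plants the published panel coordinates verbatim,
the three low-consistency horse candidates (first horse batch only),
421 shared-all ions and 80 donkey+horse ions, and pads the remaining
sharing subsets (38 D+H+C, 20 D+H+P, 8 H+C, 2 H+P, 2 H+C+P, 1 each
D+C, D+P, D+C+P — solved so the four inventories total exactly
569/575/474/453 ions; the subset composition of the padding beyond the
published counts is not published and is this package's choice).

Two separation rules make recovery targets exact rather than
probabilistic: within a 0.7 min co-elution window (cross-run RT
tolerance plus two-sided jitter) any two planted or noise peaks keep
≥ 4 Th between monoisotopic m/z (so EIC windows and isotope chains
never overlap), and co-eluting planted ions keep their neutral masses
≥ 0.2 Da away from 0/1-isotope offsets of each other (so variant
dedup cannot merge distinct ions). Layouts violating the rules are
rejection-resampled.

The market simulator draws a composition per sample from the surveyed
category frequencies, maps contents through the calibration curves to
areas with 3% relative noise, and puts absent markers at the blank
response — the calibration intercept — so inversion yields ~0 content.
(The intercepts, ~50–160 counts, *are* the blank response of the
published lines; a fixed arbitrary blank area would invert to spurious
double-digit contents.)

What the generator does not emulate: chromatographic peak shapes,
missed cleavages and hydroxyproline chemistry of real collagen digests,
mass-calibration drift, envelope overlap between co-eluting peptides,
and intensity correlation across batches. Exact planted-count recovery
therefore demonstrates the correctness of the screening logic under
its stated tolerances, not the resolution limits of real QTOF data.

## Problem sizes and numerics

The full-scale preset (594 planted ions, 15 samples, ~2000 peaks per
sample) screens in a few seconds; recovery checks run it over three
seeds. Unit and property tests use reduced layouts (5–20 ions per
class) that still exercise every sharing class. All randomness flows
through `numpy.random.default_rng` seeded from the configuration, and
identical seeds reproduce fixtures byte-for-byte. Degenerate inputs are
defined explicitly: singleton envelopes carry no charge; empty peak
tables give empty inventories; calibration requires two distinct
amounts; an all-zero HM1 reference set is an error for ratio
estimation; empty verdict lists summarise to zeros.

## Known limitations

- The published per-species ion inventories beyond the printed marker
  tables are unavailable; padding ions are synthetic and only their
  counts are faithful.
- The scalar horse-subtraction ratio cannot reproduce every published
  indirect CP value (one surveyed sample implies r ≈ 0.59 vs ≈ 0.50
  for the others).
- Reported-marker re-evaluation is m/z-only and inherits the 0.1 Da
  window's ambiguity for markers closer than that spacing.
- mzML ingestion expects centroided MS1 spectra; profile mode is out of
  scope.
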
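# Methods

## The model

A centroided high-resolution MS/MS spectrum is a list of (m/z,
intensity) peaks with a precursor m/z and charge. The precursor neutral
mass is `M = z·mz − z·M_H` with the monoisotopic hydrogen-atom mass
`M_H = 1.007825 Da`; the hydrogen-atom convention (rather than the
proton mass) is used consistently, including inside the feature clauses,
because the complementarity identity `b + y = M + 2·M_H` is written in
hydrogen units.

A fragment ion of charge z ∈ {1, 2, 3} produces an isotopic cluster of
2–3 peaks spaced `1.003/z` Th apart. Deisotoping proceeds in four
stages, applied independently per spectrum and per peak set.

### 1. Cluster search

Peak sets are maximal chains in which every consecutive pair is
separated by `1.003/z ± 0.01` Th for *some* admissible z (charges may
mix along a chain, which is exactly what interleaved envelopes of
different charge states produce). Chaining is greedy from the
lowest-m/z unassigned peak, extending by the nearest admissible
unassigned peak; each peak belongs to at most one set and set-less peaks
are carried as singletons. Within a set, every 2- or 3-subset of peaks
whose consecutive internal gaps all match `1.003/z` for one common z
(±0.01) is a candidate cluster — members may skip over interleaved
peaks of the set. With sets bounded by a few dozen peaks the O(n³)
subset scan is negligible. A consequence of maximal disjoint chains is
that a cluster can never span two sets: any admissible cross-set gap
would have merged the sets.

The tolerance 0.01 is absolute in Th and deliberately loose relative to
instrument accuracy; it is configurable (`SearchParams`), as are the
gap constant, the charge set and the cluster length bounds.

### 2. Isotopic-cluster graphs

Per peak set, a DAG over the candidate clusters plus a source and a
sink. An arc runs head → tail only if the tail's first peak has
strictly greater m/z than the head's first peak (peak identity is by
spectrum index, never by m/z proximity). Arc types:

* **black** — the tail's index range starts after the head's ends (no
  overlap). All ordered disjoint pairs are connected, not only nearest
  neighbours, so every arrangement is representable.
* **red, shared-b/c/d** — the sanctioned shared-peak patterns: a 2-peak
  head whose 2nd peak is the tail's 1st; a 3-peak head sharing exactly
  one peak which is the tail's 1st; a 3-peak head whose 2nd and 3rd
  peaks are the tail's 1st and 2nd. In every case the tail must own at
  least one peak outside the head — a cluster whose peaks are a subset
  of another's is the same ion hypothesis, not a second overlapping
  fragment, and connecting it would let the path search sweep subset
  clusters into every output.
* **red, interleaved** — no shared peak, but the tail nests strictly
  inside the head's span (two envelopes threaded through each other).
  Without this arc the no-shared-peak overlap case could never put both
  true clusters on one path, because black arcs require disjoint
  ranges. Nesting (tail's last peak before the head's last) is required
  because an unrestricted range-overlap arc lets phantom tails recruit
  peaks already claimed earlier on the path.

Source and sink connect to *every* cluster, with sink arcs weighted
zero. Since cluster scores are non-negative, this leaves the optimal
total unchanged compared to attaching only terminal clusters, while
allowing paths to stop early; combined with the tie-break below it
prevents zero-score head/tail clusters from being swept into the
output by a forced continuation.

### 3. Feature scoring

Eight variables relate two peaks x, y under the charge pairings
(z, z), (2, 1), (3, 1), (3, 2):

    diff1 = x − y             sum1 = x + y
    diff2 = x − y + M_H/2     sum2 = x + y + M_H/2
    diff3 = x − y + 2M_H/3    sum3 = x + y + 2M_H/3
    diff4 = x − 2y + M_H/3    sum4 = x + 2y + M_H/3

Each feature evaluates nine clauses over these variables; every printed
equality `expr = target + θ` is read as the symmetric window
`|expr − target| ≤ θ` with θ = 0.3 Da — a literal equality with an
additive tolerance term has no consistent interpretation. y ranges over
every peak of the spectrum except x itself; the features count distinct
satisfying y.

* **F1**: targets are the 20 monoisotopic residue masses (I/L share a
  value but both rows are kept; K and Q remain distinct), divided by
  1, 2, 3 according to the clause.
* **F2**: targets are `(M + 2i)/k + 2·M_H` for k = 1, 2, 3, where i is
  x's 0-based position in its cluster. The printed offset of 2 Da per
  isotope position is implemented verbatim; the physically motivated
  alternative (1.003 Da per position) is available as
  `FeatureParams.f2_offset_mode = "isotopic"` but is not the default.
  Note `sum2`/`sum3` are symmetric in their arguments, so their two
  argument orders coincide; the clause list keeps the printed
  structure regardless.
* **F3**: targets M_H2O = 18.010565, M_NH3 = 17.026549 (and /2, /3).
* **F4**: targets M_CO = 27.994915, M_NH = 15.010899 (and /2, /3).
* **F5**: the cluster's member intensities are normalized to unit sum
  (E). For every member after the first (the monoisotopic anchor), the
  member counts if

      min(|E_i − Tmin_i|, |E_i − Tmax_i|) / Tmean_i ≤ 0.3.

  T vectors come from the isotope model below, truncated to the
  cluster's length and renormalized per model before taking elementwise
  extremes, so 2-peak clusters are compared against 2-position shapes.
  When the cluster is scored as the tail of a shared-peak red arc, the
  partner's unit-normalized mean envelope value at the shared peak's
  *partner position* is subtracted from that peak's E first; both
  clusters are unit-normalized before subtraction (the scale coupling
  between overlapping envelopes is unknown, and unit-sum is the same
  normalization the criterion itself uses).

Per-peak score is `Σ_f ω_f F_f` with ω = (0.8, 0.5, 0.1, 0.1, 0.1) —
fitted constants taken as given, overridable in config — and the
cluster score is the sum over members (F5 contributing its per-member
indicators). The same peak can thus score differently in different
clusters: its charge hypothesis, isotope position and overlap
relationship all differ.

Arc weight = score of the arc's *tail* evaluated under the arc's
relationship. Under this reading a path's total equals the sum of its
clusters' scores, and sink arcs carry zero consistently. The scorer
memoizes F1/F3/F4 per peak, F2 per (peak, position) and envelopes per
(mass, length), since a peak typically belongs to several candidates.

### 4. Path search

The graphs are DAGs (arcs strictly increase the first-peak index), so
the maximum-weight source→sink path is found by DP over a topological
order, linear in the number of arcs. Scores within 1e-9 are treated as
tied; ties prefer fewer clusters, then the lexicographically smallest
sequence of first-member m/z. The float tolerance matters: without it,
`0.8 + 0.4` vs `1.2` round-off turns genuine ties into arbitrary
winners and defeats the fewer-clusters rule. Selected clusters become
ions (mono m/z = first member, charge = cluster z, intensity = summed
members); a peak claimed by two clusters on the path contributes its
full intensity to both by default (`intensity_split = "proportional"`
divides it equally among claimants instead). Unclaimed peaks are kept
as 1+ singletons by default, so low-intensity real fragments are never
silently dropped.

## Isotope model

Aggregated (nominal +0/+1/+2) isotope distributions are computed by
convolving per-element isotope patterns, using exponentiation by
squaring with truncation after each convolution (exact for the retained
positions). Abundances: C 0.9893/0.0107, H 0.999885/0.000115,
N 0.99636/0.00364, O 0.99757/0.00038/0.00205, S 0.9499/0.0075/0.0425.
Three extreme composition models bracket an unknown peptide fragment:
all-phenylalanine C9H9NO (carbon-rich, minimal mono fraction),
averagine C4.949H7.833O1.473N1.361S0.038 (mean; sulfur kept in this
model only), all-aspartate C4H5NO3 (oxygen-rich, maximal mono
fraction). For a target mass, C/N/O/S counts are scaled and rounded and
hydrogen absorbs the mass residual. `envelope_bounds` reports the
averagine distribution as the mean and elementwise min/max over the
three models as the bracket; the extremes of normalized vectors do not
themselves sum to one (only the mean does), which is inherent to
elementwise bracketing. Fine isotopic structure is irrelevant at 2–3
retained positions and is not modelled.

## Synthetic spectra

The generator emulates the decision problem the method faces, not an
instrument. Defaults per spectrum:

* 6 clusters, monoisotopic positions uniform in 200–1400 Th with ≥ 190
  Th separation (isolated fragment ladders; separation beyond the
  largest residue-mass window keeps cross-envelope feature firings
  structural rather than incidental), charges drawn 1+ : 2+ : 3+ =
  0.55 : 0.35 : 0.10 restricted to `(mono − M_H)·z ≤ M` (a fragment
  cannot outweigh its precursor, M = 1800 Da at 2+ by default);
* 3-peak envelopes for masses ≥ 900 Da, 2-peak below (the +2 isotope of
  lighter ions sits below a realistic detection floor); intensities
  follow the averagine mean envelope scaled log-uniformly over
  300–3000 arbitrary units;
* decoration peaks: per member, up to 2 complementary partners at F2
  clause targets for the member's true position (off-center variants
  within the ±θ window are tried when the exact target collides with
  another clause window — a real complement matches within tolerance,
  not exactly); per monoisotopic peak, one neutral-loss satellite, one
  supportive-ion satellite and one residue-ladder partner;
* noise: count = 30% of the planted envelope peaks, m/z uniform,
  intensity log-uniform between 1% and 30% of the median planted
  base-peak intensity;
* m/z jitter: Gaussian, σ = 0.003 Th, applied to every peak last
  (ground truth keeps ideal positions). `SyntheticSpec.clean()` turns
  noise and jitter off.

Three screens keep the planted truth *unambiguous*, i.e. guarantee that
the generator never manufactures evidence for a non-planted
arrangement:

1. no generated peak may fall within 0.012 Th of a position that would
   extend an isotopic chain with any existing peak;
2. cluster layouts are resampled until no envelope peak fires any
   feature clause for another cluster's envelope peak;
3. decorations and noise must stay clause-silent for
   *arrangement-critical* peaks — interior peaks of singly-claimed
   chains and all peaks of chains hosting several clusters — because
   competitor tilings count exactly those peaks more often than the
   planted arrangement does, so extra support there (and only there)
   can flip the DP. Decoration support at planted (peak, position)
   assignments is exempt: it reinforces the true arrangement.

The overlap archetypes are constructed explicitly: interleaved
(1+ triple with a 1+ pair nested between its peaks — given a 2.5×
intensity disparity, since two near-equal interleaved envelopes are
genuinely indistinguishable from one envelope at double charge),
two-shared-peak, one-shared-peak and mixed-charge sharing, with shared
peaks carrying summed intensities.

What the generator does **not** emulate: profile peak shapes and
centroiding error beyond Gaussian jitter, detector dynamic-range
effects, envelope lengths above 3, charge states above 3, chemical
noise with its own isotope structure, and realistic fragment-ladder
density (clusters are deliberately separated). Passing the recovery
batteries therefore demonstrates that the stages compose correctly and
that the arrangement search is driven by the features as designed — not
that these recovery rates transfer to instrument data.

## Evaluation

`theoretical_fragments` generates the a/b/c/x/y/z series (b = Σresidues
+ M_H at 1+; y = Σresidues + M_H2O + M_H; a = b − CO; c = b + NH3;
x = y + CO − H2; z = y − NH, matching the supportive-ion offset used by
F4) plus water/ammonia losses for b and y. Matching is greedy
one-to-one by ascending mass difference — one-to-one avoids
double-counting a theoretical peak matched by several experimental
ions, and greediness keeps TP monotone in the tolerance. By default
both sides are compared as charge-1-equivalent m/z
(`(mz − M_H)·z + M_H`), so ions of any native charge can match their
1+ theoretical counterpart; `single_charge_space=False` compares native
m/z. Precision, recall and F default to 0 on empty denominators.

## Numerical and degenerate-input choices

* DP score ties: 1e-9 absolute tolerance; deterministic tie-break
  (fewer clusters, then smallest m/z sequence).
* Zero-intensity clusters: F5 returns 0 (no normalizable envelope).
* Empty spectra produce empty ion lists; peak sets need ≥ 2 peaks;
  a peak-set graph is only built when the set has candidates.
* MGF blocks without CHARGE default to 1+ with a logged warning; MS2
  scans with several Z lines expand to one spectrum per charge
  hypothesis (downstream code assumes a single M).
* Duplicate m/z values are preserved as distinct peaks; the generator
  merges coincident planted positions (< 1e-4 Th) by summing, which is
  how shared envelope peaks arise.

## Known limitations

* Interleaved envelopes are only connectable when one nests inside the
  other's span; two interleaved 3-peak envelopes where the later one
  protrudes are not representable on a single path.
* The verbatim 2-Da-per-position offset in F2 means complements of
  higher isotope peaks are sought at targets with no physical
  counterpart; the `isotopic` mode exists but changes the constants'
  meaning.
* Scores are non-negative sums of evidence counts, so any
  positive-scoring overlapping cluster reachable on the optimal path is
  reported; in dense real spectra this inflates the output relative to
  a minimal explanation. The intensity-free features are deliberately
  insensitive to abundance, which preserves weak ions but also scores
  noise peaks that happen to sit in clause windows.
* Charges above 3+ and envelopes longer than 3 peaks are out of scope
  by construction.
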
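# Methods

## Scope and pipeline

`prodperm` models the early, purely computational stage of prodrug
design for liposome formulation: given a parent drug and a membrane
characterized by layered free-energy and diffusivity profiles, predict
where each candidate prodrug lands in the (log K, log Perm) plane and
how that position moves along a homologous series or upon polar-adduct
conjugation. The pipeline is

1. structure enumeration (`prodperm.chem`),
2. conformer diversity filtering (`prodperm.conformers`),
3. membrane profiles — synthetic here (`prodperm.profiles`) or
   user-supplied TSVs,
4. partitioning/permeability (`prodperm.isd`),
5. LBCS classification, trends and scenarios (`prodperm.lbcs`,
   `prodperm.trends`).

Conformer *generation*, molecular-dynamics membrane simulation and the
quantum-chemical (COSMO-RS-type) profile calculation are deliberately
out of scope; they belong to external engines. The packaged summary
tables (`prodperm/data/table1.csv`, `table2.csv`) carry published
partitioning/permeation values exactly as printed (two decimals, mean ±
sd over five membrane snapshots) and serve as *inputs* to the trend and
adduct-effect analyses — this package does not recompute them, and its
synthetic profiles are calibrated only to their scalar features, not
fitted to reproduce them.

## Structure enumeration

Parents are SMILES plus a table of named sites (hydroxyl, primary
amine, aromatic CH), validated against the parsed molecule. Each
operation replaces exactly one hydrogen at the site with a fragment:

| operation | fragment | net formula change |
|---|---|---|
| ester (n ≥ 2) | −C(=O)(CH₂)ₙ₋₂CH₃ on O | +CₙH₂ₙ₋₂O |
| amide (n ≥ 2) | −C(=O)(CH₂)ₙ₋₂CH₃ on N | +CₙH₂ₙ₋₂O |
| alkyl (n ≥ 1) | −(CH₂)ₙ₋₁CH₃ on aromatic C | +CₙH₂ₙ |
| fructose | β-D-fructofuranosyl via anomeric C2 | +C₆H₁₀O₅ |

Design choices, where the chemistry was genuinely open:

* Cytarabine has three hydroxyls; only the pentose C5′ primary hydroxyl
  is registered as a site, matching the study design. Other hydroxyls
  are simply not annotated.
* Fructose condenses through its anomeric (C2) hydroxyl by default: it
  makes the +C₆H₁₀O₅ delta exact and leaves the regiochemistry
  overridable (any dummy-atom fragment SMILES can be passed). The ring
  form is fixed to the β-furanose tautomer. Atom-level fidelity of
  adduct drawings is not guaranteed; formula-level behavior is.
* 5-Fluorouracil has no primary amine; its ring N–H is registered under
  the primary-amine site kind because the condensation semantics (one
  N–H replaced) are identical. Site validation therefore accepts any N
  carrying ≥ 1 H; a true primary amine carries two.
* Operations accept any chain length meeting their preconditions (odd
  lengths included); the packaged study catalog restricts itself to the
  even-carbon series (esters 2–16, amides and alkyls 2–10).

Duplicate canonical SMILES under distinct catalog names abort
enumeration: that always indicates a bad study design rather than a
legitimate collision.

## Conformer filter

The filter keeps at most 10 conformers within 5 kcal/mol (inclusive) of
the set minimum with pairwise RMSD ≥ 0.2 nm. The published method
statement leaves the algorithm open; here it is **greedy in ascending
energy** — accept a conformer iff it is inside the window and at least
0.2 nm from every already-accepted one — which is deterministic,
order-independent, and equal to the lexicographically-first maximal
feasible subset (property-tested against brute-force subset
enumeration). RMSD uses heavy atoms by default (hydrogen positions are
soft), always after optimal rigid-body superposition (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`); energy ties break by
conformer id.

## Synthetic profiles

Profiles are Gaussians on an exactly symmetric grid over [−Z, +Z]
(default Z = 40 Å, 50 layers): a central barrier (height B, σ = 8 Å),
two wells of depth m at ±20 Å (σ = 4 Å), the whole shape shifted so the
edges are exactly zero (bulk-water reference). Per-layer Gaussian noise
(default off; 0.2 kcal/mol in the demo) is drawn from a generator keyed
on (seed, snapshot id), so outputs are bit-reproducible. Homologous
series lower B and deepen m linearly per two carbons, with B floored at
zero.

D(z) is a two-region sigmoid from D_water = 5×10⁻⁶ cm²/s outside to
0.1 × D_water inside (transition at the well position, 2 Å width). No
published D(z) exists for this system; absolute log Perm values
therefore depend on this convention, while *differences* between
profiles — the quantities the analyses rest on — are insensitive to a
common D(z). The generator emulates profile anatomy, not lipid physics:
passing tests demonstrate correct model evaluation and trend recovery,
not chemical accuracy for any real membrane.

## Numerics

* Gas constant R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹; default T = 293 K, so
  one order of magnitude in K or P costs RT ln 10 = 1.3407 kcal/mol.
* log K uses the single global grid minimum, not a depth-averaged
  partition function — fidelity to the stated "directly from the
  minimum" convention.
* The resistance integral uses the composite trapezoid rule over the
  full supplied grid (the water plateau contributes negligibly since
  K ≈ 1, D = D_water there). On smooth profiles, 50 layers agree with a
  5000-layer reference within 10⁻² log units (asserted in tests);
  exact closed forms (flat membrane P = D/2L; a uniform +RT ln 10
  offset shifting log Perm by exactly −1) are reproduced to 10⁻⁹.
* Snapshot aggregation: arithmetic mean and *sample* standard deviation
  (ddof = 1) on the log scale; a single snapshot reports sd = 0 with a
  `single_snapshot` flag.

## LBCS classification

Bin precedence: yellow (log K above the membrane-trapped threshold)
first, then gray/blue (log Perm above the leakage threshold; blue iff
the user flags the compound ionizable inside the liposome cavity), then
green (log Perm ≥ the release threshold and log K inside the green
window), else red. The shipped defaults (−7.5 / −10.5 for the log Perm
thresholds; 3.5 for membrane trapping; green log K window [−2, 3.5])
are explicitly **calibration values** — the published diagram is
graphical — chosen so the study's qualitative placements hold; every
classification takes its boundary set explicitly and users should treat
the numbers as editable policy, not facts. Under these defaults the
5-fluorouracil fructose adduct lands red, i.e. formulable but not
thermally releasable — consistent with "feasible" in the qualitative
sense.

## Trends, inverse design, adduct scenarios

Series increments are computed between consecutive points rescaled to
per-2-carbon units (so uneven spacing is handled), summarized as mean ±
sample sd plus an ordinary least-squares line in carbon count. Inverse
design extrapolates linearly from the parent value with the fitted
per-carbon slope, stepping by two carbons, and reports the smallest
chain length landing inside the target interval — or an explicit
unreachable verdict (zero slope, wrong direction, step overshoot,
range exhausted).

The polar-adduct effect is classified from the parent-minus-adduct
shifts: a reduction is *significant* when it exceeds k·(propagated sd)
with k = 2 by default (configurable). The two flags (permeability,
partitioning) map onto four scenarios: permeability-only,
partitioning-only, both, neither. This is a deliberate
operationalization of a qualitative judgement; k is the only knob.

Two documented discrepancies in the packaged tables: the published
per-2-carbon acyl increment 1.44 ± 0.21 is not recoverable from the
rounded table values under any grouping (esters give 1.64, amides 1.39,
pooled 1.55) and was evidently computed from unrounded data; likewise
the narrative cytarabine log K reduction of 1.3 versus the 0.67 implied
by the table. The fixtures carry the table values unchanged.

## Problem sizes and determinism

All analyses run at desk scale: 26 enumerated structures, 50-layer
profiles, 5 snapshots per molecule, ≤ 12-conformer selection sets in the
brute-force cross-checks. Every stochastic element (profile noise,
test geometry generation) flows from an explicit integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical output
files, which the CLI demo asserts end to end.

## Known limitations

* No 3D conformer generation, tautomer/protonation enumeration, or
  synthetic-accessibility screening; generated structures are
  topological proposals.
* Neutral species only — no pH partitioning; the blue-bin ionizability
  flag is user-supplied metadata.
* Synthetic profiles carry no lipid-specific physics (phase state,
  cholesterol content, headgroup chemistry enter only through the
  user's choice of shape parameters).
* Absolute permeabilities inherit the D(z) convention; compare
  differences, not absolutes, across conventions.
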
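# Methods

## The pause–restart model

PLOR (position-selective labeling of RNA) performs T7 transcription on a
bead-immobilized template in k discrete steps. Step i supplies a subset
Sᵢ ⊆ {A, C, G, U} of the NTPs; between steps the liquid phase is exchanged,
so each step's NTP pool is independent. The package models elongation as
strictly template-directed and error-free: from a 3′ end at position p−1,
the polymerase incorporates bases p, p+1, … as long as each transcript base
is in Sᵢ, and halts with its 3′ end on the last incorporable base (the
missing NTP is *not* incorporated). This halting rule is the whole kinetic
content of the design model — misincorporation, read-through past a pause,
and carry-over of residual NTPs between steps are not modeled.

Applying the rule step by step tiles the transcript into contiguous
segments, one per step. A step whose first required base is excluded makes
zero progress ("stalled"); a schedule whose last segment stops short of the
template end is "incomplete". Both are hard errors in `build_segments` and
plain report entries in `validate_schedule`, because a partially synthesized
design can be a legitimate intermediate.

### Promoter and transcript conventions

Templates are double-stranded but entered as one printed strand. The 17-nt
class-III T7 consensus `TAATACGACTCACTATA` is searched on the given strand
and its reverse complement; exactly one hit across both strands is required
(variant or mismatched promoters are out of scope). Transcription starts at
the base immediately 3′ of the consensus (+1 = transcript position 1,
coordinates 1-based inclusive throughout) and, by convention, always runs to
the template end for the full-length product — shorter 3′ ends arise only
from termination or incomplete schedules. A transcript that does not start
with G draws a warning rather than an error, since T7 initiation on non-G
starts is inefficient but not impossible.

### Terminator annotation

The intrinsic terminator is modeled purely as its U-tract: the longest
maximal run of ≥ `min_run` consecutive U, ties broken toward the most
3′ run. `min_run` defaults to 6 — the example transcript has an internal
6-U run at 85–90 and the 8-U tract at 101–108, and the longest-run rule
selects the tract; the parameter is exposed for other templates. The
terminated product length is defined as u_start − 1 (release immediately
before the first U). Real terminated 3′ ends likely distribute across the
tract; the single-number convention is a modeling choice that matches the
one-band readout of a gel. The GC-rich hairpin upstream of the tract is
deliberately not modeled — no secondary-structure or thermodynamic scoring.

## Stoichiometric NTP batches

"1×" means exactly one RNA per template: for a stoichiometric step,
conc(b) = (count of b in the step's segment) × (DNA concentration) × fold,
zero for excluded NTPs. Fold is real-valued (0.5× gives fractional µM) and
batches are linear in fold by construction. Initiation needs a large excess
to be efficient, so the first step of a real schedule is typically an
`explicit` override that passes user concentrations through unchanged;
stoichiometric semantics are only claimed for restart steps. A label
substitution (e.g. Cy3-UTP) replaces its NTP entirely in that step and
carries the same concentration; partial doping is out of scope.

## Inverse label design

`design_label_schedule` finds a minimal-step schedule in which one step's
segment contains the label base exactly at the requested positions. A
segment [s, e] can end at e only if the base at e+1 is absent from the
segment ("valid stop"); since the label base is necessarily present, a
requested position immediately followed by the same base is not isolatable —
the polymerase cannot pause between consecutive identical residues.

The search enumerates candidate labeling segments (all valid (s, e) that
contain the label base exactly at the requested positions), tiles the prefix
[1, s−1] with a farthest-stop greedy, and closes with a single all-four-NTP
run-off step. The greedy prefix is provably minimal: moving a segment's
start rightward can only shrink its base set, so its farthest valid stop
never moves left, and the standard exchange argument applies. An exhaustive
breadth-first search over all stop placements is implemented for transcripts
≤ 64 nt and used as an independent oracle in the tests. Two documented
tie-breaks/constraints: minimal step count, then longest first segment; and
the labeling step is kept out of the initiation step whenever any
later-step design is feasible, because initiation runs with a large
non-stoichiometric NTP excess where a fluorophore analog would be wasted
and poorly incorporated.

`design_even_schedule(tx, k)` builds a complete k-step schedule with pause
boundaries at the valid stops nearest the even i·L/k splits. It exists
because alternative pause strategies (3-, 6-, 10-step reactions) are an
experimental choice: in the step-level yield model below, the realized yield
depends only on k, not on where the pauses fall, so any valid k-step
schedule is equivalent for yield analysis.

## Yield model and termination statistics

The overall single-round yield is E = Eᵢ · Eₑⁿ with Eᵢ, Eₑ ∈ (0, 1] the
per-complex initiation and per-step elongation (restart survival)
probabilities and n = k − 1 the number of post-initiation steps. Stalling is
per step, not per nucleotide — a deliberate simplification consistent with
the observation that yield decays with step count; a per-nucleotide
alternative is out of scope. "Yield decreases with n" is implemented as the
monotone decay Eₑⁿ, not literal 1/n proportionality.

The model is exactly log-linear, so fitting is unweighted ordinary least
squares on log E = log Eᵢ + n log Eₑ (no error model is assumed for the
observations). Back-transformed estimates above 1 are clipped to 1 and
flagged rather than accepted — efficiencies are probabilities. The fit
reports log-space residual summaries only; confidence intervals are out of
scope. Noiseless data are recovered to machine precision for any
(Eᵢ, Eₑ) ∈ (0, 1]² with ≥ 2 distinct n.

Termination efficiency is T/(T+FL) per replicate; the read-through ratio is
FL/T (absent when T = 0). Replicates are aggregated by averaging
per-replicate efficiencies — not pooled intensities — so lanes with
different exposures contribute equally, and the statistic is invariant to
any uniform rescaling within a replicate. The spread is the sample (n−1)
standard deviation, absent for single replicates.

### Per-length correction

Intercalating-stain signal is mass-proportional (∝ molecules × length)
while single-fluorophore signal is molecule-proportional. `molar_correct`
with `per_length` divides each intensity by its product length, converting
stain signal to per-molecule signal. Because the full-length band is longer
than the terminated band, raw stain data over-weight FL and *under-state*
the termination efficiency; the correction therefore strictly raises the
apparent efficiency whenever FL is longer than T. The default is `none`,
matching common practice of reporting relative intensities without length
normalization — the user must opt in knowingly.

## The simulator

`simulate_single_round` draws, from a single seeded
`numpy.random.Generator`, a chain of binomials over n_molecules templates:
initiation with probability Eᵢ, survival of each of the k − 1 restarts with
probability Eₑ, and, for survivors reaching the terminator, termination with
probability p_term (else run-off). Identical parameters give
bitwise-identical counts, and molecules are conserved:
initiated = Σ stalled + terminated + full_length.

The ligand response is a hyperbolic occupancy interpolation
p_term(adenine) = p₀ − (p₀ − p₁) · adenine/(K_d + adenine), a standard
single-site binding form chosen for its correct limits (p₀ at zero ligand,
p₁ at saturation, midpoint at K_d); no mechanistic claim is attached to it.
Defaults (p₀ = 0.85, p₁ = 0.55, K_d = 1 µM, Eᵢ = Eₑ = 0.9,
n_molecules = 100 000, σ = 0.05) emulate the observed regime of the assay:
~80–90 % termination without ligand, ~50–60 % at saturating adenine, yields
decaying with step count.

`emit_band_table` turns counts into a band table with independent
lognormal(0, σ) multiplicative factors per band and replicate — lognormal
keeps intensities positive, and σ = 0 reproduces counts exactly. Replicate
noise consumes one seeded stream sequentially (reproducibility over
parallelism).

What the simulator does **not** emulate: distributed terminated 3′ ends
(one T length only, matching the single gel band), kinetic competition
between RNA folding and elongation (the Mg²⁺- and NTP-speed effects seen
experimentally), the unexplained decline of total yield at high ligand,
cross-step NTP carry-over, and re-initiation (excluded by the single-round
premise). Passing round-trip tests therefore show the estimator recovers the
generating probabilities under the stated noise model — not that real gels
behave this way.

## Numerical and testing choices

Problem sizes: simulator calibration and yield-recovery checks use 100 000
molecules (binomial SE ≈ 0.001 on an efficiency, comfortably inside the
±0.02 check bands) with σ = 0.05 band noise and 3 replicates; the
halting-rule oracle comparison runs 1000 random (sequence ≤ 200 nt,
schedule ≤ 10 steps) pairs; terminator annotation is checked against a
brute-force run enumerator on 1000 random sequences. Concentrations are
reported to 0.1 µM in design sheets but kept exact internally. Hypothesis
property tests run derandomized so the suite is reproducible.

## Known limitations

Single promoter model (exact consensus only); one shared Eₑ across steps;
no per-gel lane normalization or background subtraction (densitometry is
ingested as tables); schedules are validated, not optimized for cost beyond
minimal step count; the exhaustive label-design oracle is capped at 64 nt.
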
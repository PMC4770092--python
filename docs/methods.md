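# Methods

This note documents the models implemented in `lidforce`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that affect
results. Everything quantitative stated here is computed by the package's
tests or scripts; nothing is quoted from elsewhere.

## Physical model of the assay

A single enzyme is held between two optically trapped beads through
double-stranded DNA handles. At fixed trap separation *D* the tension *F* in
the tether satisfies the force balance

    F = k_eff · (D − x_protein − x_DNA(F)),      k_eff = (1/k₁ + 1/k₂)⁻¹,

where x_DNA(F) is the worm-like-chain (WLC) extension of the handles and
x_protein the end-to-end contribution of the protein along the pulling axis.
`solve_tether_equilibrium` solves this by bracketed bisection (Brent, 1e−12
absolute / 1e−13 relative on force). When the solution falls below a slack
threshold (0.01 pN default) the tether is reported as slack with F = 0; a
purely entropic chain formally carries some tension at any positive gap, so
an exact-zero criterion would never trigger.

WLC elasticity uses the Marko–Siggia interpolation

    F(x) = (kBT/P) [ 1/(4(1 − x/L)²) − 1/4 + x/L ],

optionally with an enthalpic stretch term (x/L → x/L − F/S). Defaults:
dsDNA persistence length P = 50 nm, contour length L = 360 nm (the handle
length of the assay), inextensible; unfolded polypeptide P = 0.7 nm and
0.365 nm per residue. These are field-standard values; all are configurable,
since the actual fitted handle parameters of any given experiment differ.
Temperature defaults to 298 K, kBT = 4.114 pN·nm.

**Constant-force transform.** The raw observable is the bead deflection
signal; handle compliance makes the apparent size of a conformational change
depend on the force bias. For each sample the tension is taken from the force
channel (or inferred as k_eff × signal), the WLC handle extension and trap
deflection are subtracted from the trap separation, and the remainder is the
protein-extension coordinate. The per-sample WLC inversion uses a dense
monotone lookup table (20 000 nodes) with linear interpolation; the scalar
inverse used elsewhere is exact to 1e−9 relative. The transform refuses to
run twice on the same trace (processing history guard) unless forced.

## State detection and dwell statistics

Transitions are detected with a two-state Gaussian-emission hidden Markov
model fitted by Baum–Welch (hmmlearn backend) on the stored 30 kHz stream —
"unfiltered" means no display filtering; the 37.5 Hz low-pass
(`lowpass_display`, zero-phase fourth-order Butterworth in second-order
sections) is cosmetic only and never feeds the detector. Initialisation is a
1D two-means split of the signal; convergence at Δlog-likelihood < 1e−8 per
sample or 500 iterations. Fits whose levels collapse within 0.1 pooled
standard deviations raise a diagnostic (single-state data). Gaussian
emissions are justified by the generator's noise: block-averaged
Ornstein–Uhlenbeck noise is Gaussian.

Viterbi decoding is deterministic; dwells are the run lengths of the decoded
path. The first and last dwells of every recording are censored and excluded
from rate estimates (standard for exponential maximum likelihood). No
missed-event (dead-time) correction is applied; instead the dwell metadata
reports a dead-time diagnostic of two sample periods so the bias floor is
visible. Rates are k = 1/mean(dwell duration) at the mean force of the
originating state, with seeded nonparametric bootstrap errors (1000
resamples default).

## Kinetics and energetics

Force-dependent rates follow the Bell law k(F) = k₀ exp(F·Δx/kBT) with a
signed Δx (positive = accelerated by force; closing typically carries a
small negative Δx, opening a large positive one). Global fits are weighted
least squares on log rates (weights se/k, variance-stabilising) by
Levenberg–Marquardt (lmfit), sharing one Δx across concentrations; closing
fits one k₀ per concentration (bimolecular binding-and-closing), opening
shares a single k₀. Parameter errors are 1 s.d. from the fit covariance;
zero-force rates are the fitted intercepts with delta-method errors.

Equilibrium free energies use ΔG(open→closed) = −kBT ln(k_close/k_open),
evaluated at measurement force from the measured rates and at zero force
from the extrapolated rates. No additional elastic-work terms are added
beyond the constant-force transform; this is the package's convention, and
any residual linker-entropy contribution is a documented limitation.

Competition binding: ΔΔG([L]) = kBT ln(1 + [L]/K_D), fitted on ln K_D for
positivity. The blocked fraction 1 − τ_ref/τ_ligand expresses how much of
the open dwell the substrate occupies the enzyme (99% for 5 ms → 0.5 s).

## Fraction of full closing

The competition observable is fraction(F) = (L_full(F) − L_comp(F)) /
L_full(F). The model treats the unresolved substrate-induced fluctuations as
a two-state open/partially-closed equilibrium:

    p_closed(F) = 1 / (1 + (k₀_open/k₀_close) · exp(F·Δx/kBT)),
    fraction(F) = (Δx / L_full(F)) · p_closed(F),

with one Δx shared across concentrations and one zero-force rate ratio per
concentration. The same Δx enters the Bell exponent and the normalisation —
the single conformational change plays both roles. L_full(F) is interpolated
linearly between measured forces (scalar, callable, or table input). A fixed
alternative with complete single-lid closure (Δx = L_full/2) is fitted
alongside and the model with the smaller weighted residual sum is flagged;
fractions are never clamped during fitting.

Concentration dependence at zero force uses a four-state scheme
(open/closed × unbound/bound) with dissociation constants K_open and
K_close. The unbound conformational equilibrium is fixed (not fitted) at
opening:closing = 6 500:2 000 s⁻¹; under load the unbound closed state is
negligible, giving

    p_closed([L]) = (c·[L]/K_close) / (c·[L]/K_close + [L]/K_open + 1),
    c = 2 000/6 500,

and fraction([L]) = (Δx/L_full) · p_closed([L]) with Δx/L_full fixed from
the force fits. The saturation plateau is c·K_open/(c·K_open + K_close)
times that scale; if the data do not reach ~80% of it, K_close is flagged as
a bound only.

## Lid unfolding free energy

Constant-velocity curves show a continuous equilibrium hump (fast
folding/unfolding exchange) between a folded branch (DNA WLC alone) and an
unfolded branch (DNA and polypeptide WLC in series, contour gain ΔL_c). The
transition free energy is computed by trapezoidal integration over trap
distance: the total-system energy is the area under the folded-branch fit up
to the distance where it reaches the crossover force (10 pN default, to
suppress low-force noise) plus the area under the measured curve above it;
subtracting the unfolded-branch area over the same range cancels the linker
and trap work and leaves ΔG of the transition. With exact branch models this
rule is exact for the generator (verified to <0.01 kBT).

Branch fits exclude the transition window (13–20 pN default) widened by a
3 pN margin on each side, because in the fast-exchange limit mixed occupancy
leaks a few per cent beyond the window and would bias the unfolded-branch
fit low. The dominant error source is the fitted DNA contour length: the
baseline integrates ~500 kBT over the sweep, so per-mille contour errors
move ΔG by ~1 kBT — averaging several sweeps is recommended (the acceptance
test averages three).

Nucleotide stabilisation is fitted as ΔG([L]) = ΔG⁰ + kBT ln(1 + [L]/K_D),
sharing the binding machinery with the competition fit.

## Free-energy landscape projection

2D grids over the AMP-lid and ATP-lid opening coordinates (Å, energies
converted to kBT; 1 kcal/mol = 1/(0.0019872·T) kBT) are projected onto

    d = (d_AMP − d⁰_AMP) + (d_ATP − d⁰_ATP),

the sum of displacements from the global minimum, assuming the two lid
motions are mainly orthogonal. The combination function is a swappable
strategy (only the sum is currently registered) so alternative definitions
of the lid-to-lid coordinate can be compared; the provenance records which
one was used.
Cells are binned on d (default bin = the larger axis spacing) and reduced by
Boltzmann marginalisation −kBT ln Σ exp(−G/kBT) (default) or by the bin
minimum; both are recorded in provenance. Minimum ties break toward the
smallest coordinates and are flagged. The external load enters as
G′(d) = G(d) − F·d with pN·Å → kBT conversion through the constants object
(never hard-coded), followed by a min-shift to zero.

## Synthetic-data generator

The generator defines the study conditions and is the ground truth for every
recovery test:

| parameter | default | rationale |
|---|---|---|
| zero-force closing | 0.18 s⁻¹ per nM (bimolecular) | measured association rate of the tight-binding inhibitor |
| zero-force opening | 1 s⁻¹ | measured zero-force opening rate |
| Δx (closing / opening) | −0.1 / +1.5 nm | near-force-independent closing; opening carries most of the distance |
| contraction | 1.6 nm | full two-lid closing distance |
| trap stiffness | 0.3 pN/nm per trap | typical dual-trap values; 400 nm separation ≈ 8.4 pN bias |
| sampling | 150 kHz → block-average → 30 kHz | acquisition and storage rates of the assay |
| noise | OU, 0.4 nm s.d. at 150 kHz, 5 kHz corner | single lumped bead/tether relaxation; amplitude chosen so millisecond dwells are clearly resolvable at 30 kHz, as in the recordings |
| FEC: ΔG_fold, ΔL_c | 11.7 kBT, 3.3 nm | contour gain calibrated so the equilibrium midpoint of an 11.7 kBT transition sits near 17 pN, inside the 13–20 pN observation window |

Dwell sequences are exact Gillespie draws with rates evaluated at each
state's self-consistent tether tension (rates constant within a dwell;
intra-dwell force fluctuations do not feed back on the kinetics). Rendering
assigns each 150 kHz sample its state level, adds exact-discretisation OU
noise, block-averages 5:1, and resamples the truth path by block majority.
Force–distance curves are generated in the fast-exchange limit — the
measured force is the occupancy-weighted mean of the two branch forces,
with occupancies from the integrated branch energies — because the observed
transition is a continuous equilibrium hump; a stochastic hopping mode
exists for detection stress tests.

What the generator does **not** emulate: instrument drift, hydrodynamic
coupling between beads, multiple tethers, calibration errors, non-Gaussian
noise tails, and intra-dwell force-dependent rate modulation. Passing
recovery tests therefore demonstrates correctness of the analysis chain
under the stated statistical model, not robustness to instrument artefacts.

A note on detection benchmarks: with a 5 kHz noise corner the stored 30 kHz
samples remain appreciably correlated (neighbour correlation ≈ 0.35), which
an iid-emission HMM misreads as brief spurious excursions at low
signal-to-noise. The signal-to-noise benchmark (separation ≈ 2× stored noise
s.d.) therefore uses a noise corner near the stored-stream Nyquist (15 kHz),
where the block-averaged noise is effectively white and matches the HMM's
emission assumption; at the default corner the default amplitude keeps
detection accurate.

## Problem sizes and determinism

Recovery tests use: 12 conditions × ≥500 dwells for the global Bell fits;
25 s traces (~750 k raw samples) for the SNR-2 detection benchmark; three
averaged force–distance sweeps (800 points each, 0.1 pN noise) for the
unfolding energy; seven concentrations spanning three decades for binding
fits. These sizes were chosen so each statistical check has comfortable
power while the full suite runs in well under a minute per module. Every
stochastic step takes an explicit seed; pipeline stages derive per-condition
seeds from the global seed via `numpy.random.SeedSequence`, so identical
configs produce byte-identical reports (timers aside).

## Known limitations

- Dwell-rate estimates carry the usual missed-event bias for dwells shorter
  than ~2 samples; it is reported, not corrected.
- The equilibrium free energy omits any residual elastic-work correction
  beyond the constant-force transform.
- The unfolding-energy estimate is sensitive to the fitted DNA contour
  length (see above); single noisy sweeps scatter by ~0.4 kBT at 0.1 pN
  force noise.
- The HMM assumes fixed per-trace transition probabilities; within-trace
  force drift is not modelled.
- The projection treats the two lid coordinates as orthogonal; any coupling
  in the true geometry is absorbed into the 1D coordinate.
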
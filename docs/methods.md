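# Methods

`uisnr` computes the ultimate intrinsic signal-to-noise ratio (uiSNR) —
the best SNR any receive coil array can reach, limited only by thermal
noise from the sample itself — inside voxelized body phantoms, and
analyzes how that limit scales with the static field strength B0.

## Model

### The uiSNR quadratic form

For a position r inside the body, the uiSNR is

    uiSNR(r) = omega * M0 * dV / sqrt(4 k_B T df) * sqrt( b(r)^H Psi^-1 b(r) )

where `b(r)` is the vector of receive sensitivities B1-_i(r) =
conj(B_x - j B_y)/2 of a set of electromagnetic basis fields, and

    Psi_ij = integral_body sigma(r') E_i(r') . conj(E_j(r')) dV'

is the noise covariance — the conductivity-weighted Gram matrix of the
basis electric fields. The quadratic form `q(r) = b^H Psi^-1 b` is the
largest generalized Rayleigh quotient `|w^H b|^2 / (w^H Psi w)` over
coil weightings w: the noise-optimal combination of every field the
basis spans. As the basis approaches completeness over all source
distributions outside the body, q(r) approaches the ultimate limit.

Both the Larmor term `omega = gamma B0` and the equilibrium
magnetization `M0 = rho gamma^2 hbar^2 B0 / (4 k_B T)` (spin-1/2) are
proportional to B0, so the B0-dependent part of the uiSNR is
`B0^2 sqrt(q(r))` — the *reduced* map that all scaling analysis uses.
Proton density rho is held constant (1): spatial uiSNR variations from
rho are deliberately not modeled, so maps are electromagnetic limits,
not image-intensity predictions. The absolute-scale constants default
to T = 310 K, df = 1 Hz; they cancel in every exponent.

### Electromagnetic basis

The basis support is a *dipole cloud*: a shell of air voxels at surface
distance d in [d_min, d_max], each carrying three electric and three
magnetic point dipoles along the Cartesian axes. The discrete body
surface is defined as (distance to the nearest non-air voxel center)
minus half a voxel, floored at zero; the band is closed on voxel
centers. Defaults follow the full-scale convention d_min = 3.0 cm,
d_max = 3.5 cm; both are free parameters. For truncated (torso-section)
models a circumferential variant drops shell voxels within an axial end
margin (default 4 cm) of the cut faces, so the optimal SNR of the
section is not inflated by sources facing the nonphysical cut planes.

Each basis element is a random excitation: i.i.d. circular complex
standard normal weights over all 6 x n_shell dipoles. Element i draws
from an RNG stream keyed by (seed, i), so the first N elements of any
longer run are bit-identical (prefix stability — required for nested
convergence analysis). Fields of the weighted cloud are evaluated, the
total E inside the body is solved (below), the scattered B of the
induced contrast currents is added to the incident B, and the pair
(E_total, B1- of B_total) is stored.

### Dipole moment normalization

Moment normalization is a genuine free choice: a common rescaling of
all moments cancels exactly in q (basis-mixing invariance), but the
*relative* electric/magnetic scale changes which excitations a finite
random basis samples. With equal unit moments the electric dipoles'
conduction-screened near fields dominate Psi by orders of magnitude at
low Larmor frequencies, and a desk-scale basis (tens of elements)
cannot resolve the quiet, loop-like combinations that carry the
ultimate SNR there; the estimated maps then inherit the electric-noise
frequency scaling. `build_basis` therefore defaults to a noise-balanced
normalization: per frequency, one random all-electric and one random
all-magnetic probe excitation are solved, and each dipole type's moment
scale is set to the reciprocal RMS body-noise amplitude of its probe.
Both dipole types then contribute comparably to the noise metric at
every frequency. The probes use dedicated RNG streams derived from the
same seed, so runs remain fully deterministic; `balance_noise=False`
restores unit moments (1 A m electric, 1 A m^2 magnetic).

### Field solves

All field evaluations use the exp(+j omega t) time convention, complex
permittivity `eps_c = eps0 eps_r - j sigma/omega`, and the free-space
scalar Green's function `g(r) = exp(-j k r)/(4 pi r)`; z is the B0
axis. Two translation-invariant kernels cover everything: the dyadic
`(I + grad grad / k^2) g` (electric moments -> E; magnetic moments ->
B) and the cross kernel `(1 + jkr) g / r (r_hat x .)` (electric
moments / volume currents -> B; magnetic moments -> E). On a regular
voxel grid both are block-Toeplitz and are applied exactly by
zero-padded FFT convolution; incident fields of a whole cloud cost a
dozen FFTs per element.

The total field inside the heterogeneous body satisfies the E-field
volume integral equation `E_tot = E_inc + G[chi E_tot]` with contrast
`chi = eps_c/eps0 - 1`. Discretization: voxel-constant (pulse) basis
with collocation at voxel centers; off-diagonal couplings are
`k0^2 dV G(R)` at the centroid; the diagonal is the analytic
equal-volume-sphere self term

    g_self = (2/3)(1 + j k a) exp(-j k a) - 1,   a = (3 dV / 4 pi)^(1/3),

whose static limit is the sphere depolarization factor -1/3 and whose
small-cell imaginary part reproduces the radiation-damping term
-k^3 dV/(6 pi). A single-voxel scatterer solves in closed form as
`E_tot = E_inc / (1 - g_self chi)`, which the tests pin down.

Backends: `dense` assembles the 3N_body x 3N_body matrix and
LU-factorizes once per frequency, after which every basis excitation is
a cheap triangular solve — robust at the lowest Larmor frequencies,
where `|chi| ~ sigma/(omega eps0)` reaches several hundred and Krylov
iterations crawl. `fft_iterative` runs matrix-free BiCGSTAB with the
Toeplitz operator on the body bounding box (relative tolerance 1e-6,
max 2000 iterations, zero initial guess by default) and scales to grids
where the dense matrix would not fit. `auto` (default) picks dense up
to 2600 body voxels. Both backends satisfy the same discrete equation;
they agree to 1e-10 on small grids and the operator applications agree
to machine precision.

The scattered magnetic field of the induced current
`J_eq = j omega eps0 chi E_tot` is the cross-kernel convolution
`B_sc = -mu0 X[J_eq dV]`; the self-cell contribution vanishes by
symmetry (a uniform current in the equal-volume sphere produces no B at
its own center).

### Noise covariance inversion and convergence

Psi is accumulated in double precision and symmetrized; it is Hermitian
PSD by construction. Leading n x n blocks are pseudo-inverted by
Hermitian eigendecomposition with a relative eigenvalue floor (default
1e-12): random bases become numerically rank-deficient before N reaches
the field-space dimension, and the floor keeps q monotone along nested
prefixes up to ~1e-9 relative tolerance.

Convergence is assessed exactly as a practitioner would: maps at the
full basis size N and at N - dN (dN default max(1, round(N/30)),
mirroring a 100-of-3000 ratio at full scale) give a per-voxel percent
change, maximized over all simulated field strengths; voxels at or
below the threshold (default 1%) form the convergence mask. Voxels with
zero SNR are excluded and flagged.

### Power-law scaling

Per voxel, `S(B0) = a B0^alpha` is fitted by Levenberg-Marquardt
(MINPACK through scipy) on the linear scale, initialized from the
log-log least-squares line, with tolerance 1e-10 and a 500-iteration
cap; with noise the linear-scale LM result differs from the log-log
line and the LM result is reported. The B0 grid {0.55, 1.5, 3, 5, 7,
10.5, 11.7, 14} T splits into a low-field regime (0.55-3 T, near-field,
alpha ~ 1 in large body models) and a high-field regime (5-14 T,
far-field, alpha ~ 2); the two regimes are fitted independently.
Adjacent-field behavior is summarized by the effective exponent
`log(S_hi/S_lo)/log(B0_hi/B0_lo)`, computed per voxel and averaged
within a tissue (mean of per-voxel exponents, not the exponent of the
mean factor — the two differ under heterogeneity, and the per-voxel
mean is the convention used for all tables). Tissue statistics use
population standard deviations over converged, masked voxels; label
unions (whole body, torso) are recomputed over pooled voxels.

X-nuclei conversion: a frequency window observed for protons maps to
any nucleus by `B0 = f / (gamma/2pi)`; a small table of gyromagnetic
ratios ships with the package.

## Synthetic phantoms

The generators emulate the *structure* of segmented anatomical voxel
models at desk scale, not their anatomy: a homogeneous sphere (single
tissue, air margin sized to hold the dipole shell) and a torso stand-in
(elliptic muscle cylinder, lateral fat shell, ellipsoidal organs with
later-listed organs overwriting earlier ones, truncated along z so the
circumferential shell applies). Voxels are cell-centered, 0-based,
position = origin + index * voxel_size; every phantom keeps a one-voxel
air frame. A built-in dielectric table (fat, muscle, inflated lung,
liver, cortical bone, saline) is tabulated at the eight proton Larmor
frequencies of the B0 grid with representative dispersive trends; it is
configuration, not measurement, and can be replaced by a user CSV.
Between tabulated frequencies, log-log interpolation is available but
off by default (exact lookup is required unless requested); entries
with non-positive values fall back to linear interpolation.

What passing tests on these phantoms do *not* show: anatomical
realism, tissue-specific exponent values, or convergence behavior of
full-scale (~10^6-voxel, 3000-basis) runs. They do validate every
operator, the determinism contract, and the qualitative field-scaling
physics.

## Reference problem sizes

The shipped analyses use a 12-cm saline sphere at 8 mm isotropic
resolution (1791 body voxels in a 25^3 grid), a 3.0-3.5 cm dipole shell
(648 shell voxels, 3888 dipoles), 48 basis elements, and six field
strengths {0.55, 1.5, 3, 7, 10.5, 14} T; the full pipeline runs in
about two minutes on one CPU core. These sizes were chosen so that the
dense backend's one-time factorization per frequency dominates and the
whole analysis stays interactive.

## Known limitations

* **Finite-basis bias.** At 48 random elements the quadratic form is a
  strict lower bound on the ultimate limit and is not converged even at
  the sphere center (the 1% mask is empty there); the shortfall varies
  with frequency, which biases fitted exponents. Full-scale studies use
  thousands of elements for exactly this reason.
* **Conductive screening at desk scale.** For a homogeneous ~1 S/m
  saline ball the RF skin depth at 128 MHz (~4.4 cm) is below the 6-cm
  center depth, so even the true low-field scaling at the center is
  sub-linear (the computed center exponent is ~0.6 over 0.55-3 T,
  against ~1 reported for heterogeneous torso models, where
  low-conductivity fat pathways and body-scale focusing weaken the
  attenuation). The qualitative transition — high-field exponent above
  low-field exponent — is reproduced.
* **Discretization.** Pulse-basis collocation with the centroid
  approximation is low-order; at 14 T the in-medium wavelength in
  saline is ~7 voxels at 8 mm resolution, marginal by the usual
  10-voxels-per-wavelength rule. The self term assumes an equal-volume
  sphere, exact only in the static limit.
* **Scope.** No proton-density weighting, no transmit/SAR analysis, no
  parallel-imaging (SENSE/g-factor) limits, no GPU or out-of-core
  execution.
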
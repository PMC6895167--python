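# Methods

## Coordinate and sampling conventions

The world origin sits on the rotation axis at detector mid-height;
lengths are physical units (µm throughout the defaults).  Detector
indices are 0-based, a pixel spans `[i-0.5, i+0.5)` and continuous
coordinates round half-even.  Projection angles are uniform over
`[0, π)` — a 180° scan; 360° scans are out of scope.  The
centre-of-rotation offset is a signed horizontal shift of the axis image
on the detector, in pixels, applied as a pure translation (no tilt).
For angle θ and point `(x, y, z)`:

```
u = (-x sinθ + y cosθ)/pixel_size + (cols-1)/2 + cor_offset
r =  z/pixel_size + (rows-1)/2
```

The detector-centring convention is a package decision (no published
convention exists for it); all oracle tests are built on the same
contract, so any consistent alternative would merely re-index.

## Slice-restricted FBP

Backprojection is voxel-driven: every slice-grid point is projected onto
the detector per angle and sampled bilinearly, with zero contribution
outside the detector (a well-defined off-detector contract).  The angle
loop runs in fixed ascending order, so sums are deterministic
run-to-run.  The continuous backprojection integral over `[0, π)` is
discretised with a single global scale π/N_φ applied after the angle
sum; the uniform-cylinder calibration test validates the scale (recovery
within 2% at the default test sizes, against a 5% acceptance band).  An
instrumented counter verifies the Θ(n²·N_φ) cost claim exactly.  The
full-volume FBP applies the identical sampling rule to every voxel and
exists purely as the reference oracle: an axial slice equals the
corresponding volume plane to 1e-10 (in fact bitwise, since the
arithmetic is shared).

The partition-sum form splits the angles into contiguous groups,
accumulates unscaled partial slices independently (the distributed-GPU
pattern) and applies the global scale once after summation; linearity of
backprojection makes it equal to the monolithic slice up to summation
order (≤1e-9 relative in tests, typically 1e-15).

## Ramp filter

The discrete Ram-Lak kernel is the standard spatial sequence — 1/4 at
lag 0, −1/(πm)² at odd lags, 0 at even lags — scaled by 1/pixel_size;
sampling the spatial sequence rather than |ν| avoids the well-known DC
bias.  One refinement: the infinite sequence sums exactly to zero, but
truncation to the padded length reintroduces a DC residual of order
2/(π²·pad).  That residual is subtracted uniformly from the taps so the
discrete kernel keeps the ramp's exact zero DC gain (a periodically
extended constant row filters to zero at machine precision).  Note that
with the zero-padded *linear* convolution used here, a finite constant
row still produces an edge response — that is the correct behaviour of
the convolution, not a DC leak.  Rows are zero-padded to the next power
of two ≥ 2× the row length, which kills circular wrap-around and keeps
transforms fast; the Fourier path equals direct spatial convolution with
the same taps to better than 1e-9.  Shepp-Logan is the ramp × sinc
window; `cutoff` (fraction of Nyquist, default 1) hard-limits the band.

Filtering is per-row and per-projection independent, which is what makes
the streaming design work: each arriving message can be preprocessed in
isolation, and zero-filled (dropped) projections stay zero in the
filtered buffer.

## Preprocessing chain and dropped messages

Raw → transmission → line-integral → filtered is enforced by a state tag
on the frame; flat/dark correction clamps transmission to a floor
(default 1e-6) so the log stays bounded on dead pixels.  Paganin phase
retrieval operates on transmission *instead of* the negative log (states
enforce the mutual exclusion): per projection,

```
T = -(1/μ) ln( F⁻¹[ F[I/I₀] / (1 + (λ d δ / 4πβ) |k|²) ] ),   μ = 4πβ/λ
```

with |k| the angular spatial frequency of the detector raster.  Its
zero-frequency gain is exactly 1, and a 16×16 dense-DFT oracle pins the
transfer function to 1e-10.

Dropped projections are zero-filled by the streaming layer and tagged on
the frame (`missing_angles`); the preprocessing chain forces those
angles back to zero *after* filtering.  Zeroing must happen in the
filtered domain: a zero raw image would otherwise pass through the
clamp floor and the log into a large spurious line integral.  With zeros
in the filtered buffer, backprojection simply ignores the missing
angles, and a drop fraction f scales the reconstructed intensity by
(1 − f) — measured over the inscribed field-of-view disc of the slice,
the rotation-invariant domain on which per-angle contributions are
equal (on the full square raster the equality only holds to a few per
cent, because a square is not rotation-invariant).

## Streaming contract

Transport is an in-process message list honouring exactly the
guarantees the real publish/subscribe layer provides: lexicographic
`(frame, angle)` order, at-most-once delivery, no completeness.  Frame
completion is declared when the first message of a later frame arrives
or the stream ends; the passive buffer (missing angles zero, counted in
`drop_count`) then becomes the active buffer in a single assignment, so
a reader between completion callbacks never sees a mixture of two
frames.  Messages from an earlier frame after a later one began raise a
protocol error — intermixed frames are a contract violation here, not a
condition to be silently absorbed, mirroring the interim inter-scan-wait
solution used in practice.  A decimation parameter forwards only every
Nth frame for load shedding.

## Synthetic data: what it emulates and what it does not

Ellipsoid phantoms give closed-form sinograms: each detector sample is
the exact density-weighted chord length from the quadratic ray-ellipsoid
intersection, sampled at pixel centres with no supersampling (matching
the backprojector's resolution assumptions).  Acquisition follows
Beer-Lambert, `raw = dark + (flat − dark)·exp(−line integral)`, with
optional seeded Poisson noise on detected counts (off by default — the
oracle tests need the noiseless chain).

One consequence of pixel-centre sampling: the continuum statement "total
sinogram mass is angle-independent" holds only to the quadrature error
for generic phantoms (empirically ~h^2.5: ~1e-3 on a 64² detector, 4e-5
at 256²); it is exact for centred rotationally symmetric phantoms.  The
tests assert both regimes rather than pretending the discrete sum
conserves mass to machine precision.

The wicking sequence emulates water rising through a vertical bundle of
parallel fibres (a yarn imaged end-on).  Study conditions, chosen once:
10 fibres of radius 16 µm in a 90 µm bundle, attenuation 0.02 µm⁻¹ for
fibre and water (keeps line integrals O(1), physically plausible for a
polymer at synchrotron energies and safely above the transmission clamp
floor), front speed 20 µm/frame starting at −100 µm, fill jitter 0.3.
Fibres are ellipsoids with a very large vertical semi-axis (one
closed-form projector covers everything); fibre and pore positions come
from seeded rejection packing with explicit clearances, so layouts are
collision-free and bit-reproducible.  Each pore's water column is a
stack of squat ellipsoids (vertical semi-axis = one frame's rise,
anchored to a fixed lattice) plus a slightly narrower moving cap; the
cap's sweep is always inside the lattice laid down one frame later,
which makes the material region provably monotone in time and gives the
front a near-full cross-section within one frame of crossing a probe
height.  The generator records the front height h(t) per frame as
ground truth.

What the phantom does *not* model: Fresnel edge enhancement, detector
point spread, polychromatic beam effects, real yarn pore connectivity or
capillary dynamics.  Passing tests therefore demonstrate that the
reconstruction and feedback *chain* recovers programmed events at the
achievable resolution — not that the generator reproduces any measured
uptake curve.

## Analysis and feedback

Otsu's threshold is the histogram-bin edge maximising the between-class
variance over the image's value range (256 bins by default).  The
criterion `w₀w₁(μ₀−μ₁)²` equals `(m₀w₁ − m₁w₀)²/(w₀w₁)` in histogram
moments and is invariant under the affine bin-index→bin-centre map, so
it is evaluated in exact integer arithmetic with cross-multiplied
comparisons: the maximiser and the first-edge tie-break (ties arise from
splits through empty bins) are exact rather than dependent on float
summation order.  Constant images are rejected.

Material = pixels at or above the threshold (slices are
attenuation-like, material is bright; ties count as material).  The
threshold is computed once on the first, dry frame and held constant.
Front arrival is the first frame whose material fraction exceeds the
median of the first `window` frames by `rise`; the state machine moves
idle → recording on bottom-slice arrival and recording → stopped when
both slices' fractions vary by at most `plateau_tol` over the last
`plateau_window` frames.  Defaults — rise 2% of slice area, plateau_tol
0.5%, plateau_window 5 frames, baseline window inside the state machine
reusing plateau_window — are package decisions (no published values
exist); all are configuration-exposed.  Detection lands on the frame
*after* the geometric crossing when the front tip has zero cross-section
at the crossing frame itself, which is within the ±1-frame contract the
tests assert.

## Validation sizes and numerical tolerances

The validation suite runs at desk scale: N_φ ≤ 96, detectors ≤ 96×96,
slice rasters ≤ 96, previews ≤ 32³, 15-frame wicking sequences — sizes
at which every oracle comparison is exact or deterministic and the whole
suite completes in well under a minute.  Key tolerances: slice vs
volume restriction 1e-10 (shared arithmetic, effectively bitwise); ramp
Fourier vs direct convolution 1e-9 relative; partition sums 1e-9
relative (summation order only); cylinder density recovery 5%;
drop-intensity scaling 1%; Otsu vs exhaustive search exact; front
arrival ±1 frame.  Degenerate inputs are defined, not accidental: empty
phantoms are vacuum, empty angle groups contribute zero partials,
constant images are rejected by Otsu, and a zero-frame stream produces
empty artifacts cleanly.

## Known limitations

Cone/fan-beam geometries, rotation-axis tilt, detector distortion, ring
and stripe artefacts, multi-distance phase retrieval, iterative
reconstruction and GPU execution are all out of scope.  The streaming
layer models the delivery contract, not a wire protocol.  Interpolation
is bilinear only; no attempt is made to reproduce the absolute
throughput of any particular hardware.
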
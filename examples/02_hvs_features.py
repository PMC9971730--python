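"""Extract the five HVS-inspired features for increasing blur.

Each feature is 1.0 for an identical pair and decreases as motion blur
destroys phase structure, gradients, saliency agreement, local information
and block contrast.
"""

from giqe import (
    BlurSpec,
    SceneConfig,
    apply_motion_blur,
    extract_features,
    generate_synthetic_source,
    make_motion_psf,
)

source = generate_synthetic_source(SceneConfig(seed=1)).pixels

print(f"{'L':>3} {'F_LSF':>7} {'F_VSF':>7} {'F_LGF':>7} {'F_MIF':>7} {'F_NSF':>7}")
fv = extract_features(source, source)
print(f"{0:>3} " + " ".join(f"{v:7.4f}" for v in fv.to_array()))
for L in (5, 10, 15, 20, 25):
    blurred = apply_motion_blur(source, make_motion_psf(BlurSpec(L, 60.0)))
    fv = extract_features(source, blurred)
    print(f"{L:>3} " + " ".join(f"{v:7.4f}" for v in fv.to_array()))

# Every column starts at 1.0000 (identical pair) and decreases
# monotonically in L — the monotone degradation the regressor learns from.
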
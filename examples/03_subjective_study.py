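"""Synthesize a small subjective study and compute screened MOS values.

A 15-rater panel (per-rater bias, noise, occasional lapses) scores images
whose latent quality follows the blur length; box-plot screening removes
outlying scores before the mean opinion score is taken.
"""

from giqe import compute_mos, default_panel, screen_outliers, simulate_raters, true_quality

panel = default_panel(seed=42)
print(f"panel: {len(panel)} raters, biases "
      f"{min(r.bias for r in panel):+.2f}..{max(r.bias for r in panel):+.2f}")

print(f"\n{'L':>3} {'q_true':>7} {'raw scores':>32} {'kept':>5} {'MOS':>6}")
for L in (0, 5, 10, 15, 20, 25):
    q = true_quality(L)
    raw = simulate_raters(q, panel, seed=100 + L, image_id=f"L{L}")
    kept = screen_outliers(raw)
    rec = compute_mos(kept)
    raw_str = "".join(str(s.score) for s in raw)
    print(f"{L:>3} {q:>7.2f} {raw_str:>32} {rec.n_raters_used:>5} {rec.mos:>6.2f}")

# MOS tracks the latent quality: ~5 for the pristine image, ~3 at the
# usable/unusable boundary (L = 15), below 2 at the strongest blur.
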
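"""Synthesize a skin-like texture with prescribed GLCM statistics and
measure it back.

The generator inverts the GLCM contrast/homogeneity formulas into a
symmetric distribution of horizontal neighbour steps, lays out a gray
image realising that step multiset, and the analysis side recovers the
requested statistics from the co-occurrence matrix.
"""

from hyperskin import GLCMParams, brightness, glcm, glcm_contrast, glcm_homogeneity
from hyperskin.simulate import pattern_synthesize, solve_step_distribution

target_contrast, target_homogeneity, target_brightness = 5.86, 0.56, 143.33

dist = solve_step_distribution(target_contrast, target_homogeneity)
print("step distribution (neighbour gray-level differences):")
for e, p in zip(dist.support, dist.probs):
    print(f"  P(e = {e:+d}) = {p:.4f}")

img = pattern_synthesize(target_brightness, dist, shape=(64, 64), seed=42)
m = glcm(img, GLCMParams())  # d=1, theta=0deg, 256 levels, asymmetric

print()
print(f"target  brightness/contrast/homogeneity: "
      f"{target_brightness:.2f} / {target_contrast:.2f} / {target_homogeneity:.2f}")
print(f"measured brightness/contrast/homogeneity: "
      f"{brightness(img):.2f} / {glcm_contrast(m):.4f} / {glcm_homogeneity(m):.4f}")
print()
print("Contrast is the mean squared gray-level jump between horizontal")
print("neighbours; homogeneity is the mean of 1/(1+|jump|). A perfectly")
print("uniform patch has contrast 0 and homogeneity 1.")
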
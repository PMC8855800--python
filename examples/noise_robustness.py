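"""Accuracy of the mitral measurement under segmentation-like boundary noise.

Runs the seeded 100-phantom benchmark (0.5 mm/px, 0.5 px boundary noise) and
prints the mean relative and absolute error of the phase-selected mitral
annular diameter against exact truth — the pipeline's headline accuracy.
"""

from cinemorph.experiments import mitral_accuracy_suite

suite = mitral_accuracy_suite(n_phantoms=100, seed=1)
print(f"phantoms: {suite['n_phantoms']}")
print(f"mean relative error: {suite['mean_relative_error_pct']:.3f} %")
print(f"mean absolute error: {suite['mean_absolute_error_mm']:.3f} mm")
print(f"max absolute error:  {suite['max_absolute_error_mm']:.3f} mm")
# A mean error of a few tenths of a millimetre at 0.5 mm/px means the
# measurement is accurate to roughly half a pixel despite boundary jitter.
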
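"""End-to-end accuracy comparison on a regenerated phantom suite.

Runs the full harness at reduced scale: two 200x200 images with 5 and 12 px
fibers, adaptive windows against two fixed windows, errors scored against
ground truth.  Prints the summary table that run_comparison assembles
(method, window, mean error per image and pixel-pooled).
"""

from fiborient import PhantomSpec, run_comparison

spec = PhantomSpec(
    dims=(200, 200), diameters=(5.0, 12.0), fiber_extent="span",
    min_gap=8.0, seed=21,
)
report = run_comparison(spec, window_sizes=(11, 41), n_images=2, seed=21)

cols = ["method", "window", "kind", "mean_error_deg", "pooled_error_deg", "n_pixels"]
print(report.summary[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()
print("per-diameter breakdown (deg):")
print(report.per_diameter.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# Window 0 denotes the adaptive (2d+1) mode.  The n_pixels column tells as
# much as the errors: the 11 px window only answers for a fraction of the
# pixels (it abstains where it cannot resolve the 12 px fiber), while the
# adaptive rows answer for the most pixels at uniformly low error.  (With
# only two well-separated fibers a generous 41 px window also works; its
# weakness — mixing neighboring structures — needs denser fields to show.)
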
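"""Measure endosome polarity end to end on a synthetic control movie.

Renders a confined-control scene whose true endosome angles put 50% of
spots within 45 degrees of the movement direction, then runs the full
pipeline: segment nuclei, track them, detect endosome spots, express
each spot in the per-frame nucleus-velocity polar frame, pool the
angles, and test uniformity with Rao's spacing test.  A front-quadrant
fraction near 0.50 with P < 0.001 reproduces the polarized (confined)
phenotype; a uniform distribution would give ~0.25 and a large P.
"""

from endopolar import SceneParams, generate_scene, render_movie, run_polarity_pipeline

params = SceneParams(n_cells=6, n_frames=20, seed=11).with_front_fraction(0.5)
truth = generate_scene(params)
stack, _ = render_movie(truth, channels=("nucleus", "endosomes"))

result = run_polarity_pipeline(
    stack, params.nucleus_radius, params.spot_sigma, rao_seed=1
)
dist = result.distribution
print(f"tracked nuclei: {len(result.tracks)}")
print(f"pooled endosome observations: {dist.n_endosomes}")
print(f"front-quadrant fraction: {dist.front_quadrant_fraction:.3f} "
      "(0.25 would be unpolarized)")
print(f"Rao's spacing: U = {result.rao.U:.1f} deg, "
      f"P = {result.rao.p_value:.4g} ({result.rao.mc_replicates} MC replicates)")
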
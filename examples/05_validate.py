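"""Validate projections against richness reconstructed from the maps.

Two comparisons on repeated 5000-cell draws from non-wilderness cells:
SR_lu against the observed richness SR_obs, and the projected loss dSR
against the reconstructed realized-plus-impending loss SR_threat + SR_ext
(restricted to Red-List-covered cells). An OLS slope below one means the
projection under-predicts the reconstruction.
"""

from serloss.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1))
taxon = res["taxa"]["bird"]

for name, rep in (("SR_lu vs SR_obs", taxon["validation_lu"]),
                  ("dSR vs SR_thr+ext", taxon["validation_delta"])):
    per = ", ".join(f"{r:.2f}" for r, _, _ in rep.per_draw[:5])
    print(f"{name}:")
    print(f"  {rep.n_draws} draws of {rep.n_per_draw} cells from "
          f"{rep.domain_mask_cells} eligible cells")
    print(f"  per-draw r (first 5): {per}")
    print(f"  pooled r = {rep.pooled_r:.3f} (p = {rep.pooled_p:.2g}, "
          f"n = {rep.pooled_n} unique cells)")
    print(f"  slope = {rep.slope:.3f} "
          f"({'under' if rep.slope < 1 else 'over'}-prediction), "
          f"intercept = {rep.intercept:.2f}")
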
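"""Full refinement pipeline orchestration.

The stages run in a fixed order:

1. adaptive remeshing initialization (``rar_remesh``),
2. global aspect-ratio improvement (``improve_aspect_ratios``),
3. cut invalid regions at 15 degrees,
4. fill the holes,
5. smooth the newly filled regions,
6. cut invalid regions at 30 degrees,
7. fill the holes,
8. smooth the newly filled regions,
9. surface repair.

If the result still contains triangles with an angle below 30 degrees
(equivalently, above 120 degrees — a triangle with a corner over 120 must
have one under 30), the 30-degree cut/fill/smooth trio is repeated up to
``max_outer_retries`` times with fresh smoothing seeds before giving up.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .aspect_ratio_opt import improve_aspect_ratios
from .cut_fill import cut_and_fill
from .errors import AngleBoundError, NonManifoldError, NotClosedError
from .local_smooth import SmoothingSchedule, smooth_filled_regions
from .mesh_core import QualityReport, TriangleMesh, quality_report
from .rar_init import rar_remesh
from .repair import surface_repair

__all__ = ["PipelineConfig", "remesh_molecular_surface"]

log = logging.getLogger("molremesh")


@dataclass
class PipelineConfig:
    """Thresholds and budgets for the full pipeline.

    ``theta_round1``/``theta_round2`` are the small-triangle thresholds of
    the two cut-and-fill rounds (degrees); ``epsilon`` is the sizing-field
    error tolerance (defaults to 0.002 x the bounding-box diagonal).
    """

    theta_round1: float = 15.0
    theta_round2: float = 30.0
    epsilon: float | None = None
    rar_iterations: int = 5
    ar_passes: int = 3
    schedule: SmoothingSchedule = field(default_factory=SmoothingSchedule)
    max_repair_rounds: int = 5
    max_outer_retries: int = 10

    def __post_init__(self):
        if not (0.0 < self.theta_round1 <= self.theta_round2 < 60.0):
            raise ValueError("need 0 < theta_round1 <= theta_round2 < 60")
        for name in ("rar_iterations", "ar_passes", "max_repair_rounds", "max_outer_retries"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _derived_schedule(base: SmoothingSchedule, salt: int) -> SmoothingSchedule:
    return SmoothingSchedule(
        epsilon=base.epsilon,
        deltas=base.deltas,
        directions_per_step=base.directions_per_step,
        seed=(base.seed + salt) % (2**31),
    )


def remesh_molecular_surface(
    mesh: TriangleMesh, config: PipelineConfig | None = None
) -> tuple[TriangleMesh, QualityReport, QualityReport]:
    """Run the full refinement pipeline on a closed edge-manifold mesh.

    Returns (refined mesh, before-report, after-report).  Raises
    AngleBoundError (carrying the partial result) when the retry budget
    is exhausted without reaching the [30, 120]-degree angle bound.
    """
    if config is None:
        config = PipelineConfig()
    if not mesh.is_edge_manifold:
        raise NonManifoldError("pipeline input must be edge-manifold")
    if not mesh.is_closed:
        raise NotClosedError("pipeline input must be closed")

    before = quality_report(mesh)
    # the projection reference is the input with its narrow regions (thin
    # bridges/tubes of tiny triangles) removed: those are artifacts the
    # method deletes, and projecting onto them would drag patches into the
    # interior
    from .cut_fill import detect_narrow_regions

    narrow = detect_narrow_regions(mesh, config.theta_round1)
    if narrow:
        drop = {f for r in narrow for f in r.faces}
        keep = [i for i in range(mesh.n_faces) if i not in drop]
        reference = TriangleMesh(mesh.vertices, mesh.faces[keep], validate=False)
        log.info("reference excludes %d narrow-region faces", len(drop))
    else:
        reference = mesh

    log.info("step 1: rar_remesh")
    current = rar_remesh(mesh, epsilon=config.epsilon,
                         iterations=config.rar_iterations, reference=reference)
    log.info("step 2: improve_aspect_ratios")
    current = improve_aspect_ratios(current, passes=config.ar_passes, reference=reference)

    log.info("step 3: cut invalid regions (theta=%g)", config.theta_round1)
    current, patches = cut_and_fill(current, config.theta_round1, reference=reference)
    log.info("step 4: fill holes (%d patches)", len(patches))
    log.info("step 5: smooth new filled regions")
    current = smooth_filled_regions(current, patches, config.schedule, reference=reference)

    log.info("step 6: cut invalid regions (theta=%g)", config.theta_round2)
    current, patches = cut_and_fill(current, config.theta_round2, reference=reference)
    log.info("step 7: fill holes (%d patches)", len(patches))
    log.info("step 8: smooth new filled regions")
    current = smooth_filled_regions(
        current, patches, _derived_schedule(config.schedule, 1), reference=reference
    )

    log.info("step 9: surface repair")
    current = surface_repair(current, max_rounds=config.max_repair_rounds,
                             schedule=config.schedule, reference=reference,
                             raise_on_failure=False)

    def _score(rep: QualityReport):
        return ((rep.n_self_intersecting_pairs or 0), rep.pct_below_30,
                max(rep.theta_max, 120.0))

    def _ok(rep: QualityReport) -> bool:
        return (rep.pct_below_30 == 0.0 and rep.theta_max <= 120.0
                and (rep.n_self_intersecting_pairs or 0) == 0)

    report = quality_report(current)
    best_mesh, best_report = current, report
    retries = 0
    # retries chain: each round continues from the previous round's result
    # (the adaptive remeshing step keeps re-equalizing the mesh, so rounds
    # compound instead of spiraling); the best state is kept as the
    # fallback if the budget runs out
    stalled = True  # entering the loop means the plain rounds plateaued
    prev_score = _score(report)
    while not _ok(report):
        if retries >= config.max_outer_retries:
            raise AngleBoundError(best_mesh, best_report)
        retries += 1
        log.info("retry %d%s: repeating the %g-degree round (pct_below_30="
                 "%.3f, theta_max=%.2f, intersections=%s)",
                 retries, " (with remeshing)" if stalled else "",
                 config.theta_round2, report.pct_below_30,
                 report.theta_max, report.n_self_intersecting_pairs)
        if stalled:
            # plateau breaker: residual sub-30-degree faces concentrate
            # where the local edge length exceeds the curvature-adaptive
            # target; one adaptive remeshing iteration restores the right
            # density (repair follows immediately — remeshing carries no
            # intersection guard)
            current = rar_remesh(current, epsilon=config.epsilon, iterations=1,
                                 reference=reference)
            current = surface_repair(
                current, max_rounds=config.max_repair_rounds,
                schedule=_derived_schedule(config.schedule, 51 + retries),
                reference=reference, raise_on_failure=False)
        current, patches = cut_and_fill(current, config.theta_round2,
                                        reference=reference)
        current = smooth_filled_regions(
            current, patches, _derived_schedule(config.schedule, 1 + retries),
            reference=reference,
        )
        quick = quality_report(current, count_intersections=False)
        if quick.pct_below_30 > best_report.pct_below_30 + 2.0:
            # the round wrecked the mesh; revert before paying for repair
            # and intersection counting on the wreck
            log.info("retry %d: reverting to the best state (pct %.3f)",
                     retries, quick.pct_below_30)
            current, report = best_mesh, best_report
            prev_score = _score(best_report)
            stalled = True
            continue
        current = surface_repair(current, max_rounds=config.max_repair_rounds,
                                 schedule=_derived_schedule(config.schedule, 101 + retries),
                                 reference=reference, raise_on_failure=False)
        report = quality_report(current)
        log.info("retry %d result: pct_below_30=%.3f theta_max=%.2f "
                 "intersections=%s", retries, report.pct_below_30,
                 report.theta_max, report.n_self_intersecting_pairs)
        score = _score(report)
        stalled = not score < prev_score
        prev_score = score
        if score < _score(best_report):
            best_mesh, best_report = current, report
        elif (report.pct_below_30 > best_report.pct_below_30 + 2.0
              or (report.n_self_intersecting_pairs or 0)
              > (best_report.n_self_intersecting_pairs or 0) + 10):
            # catastrophically worse round: abandon the chain and restart
            # from the best state (mildly worse rounds stay chained — the
            # remeshing step often needs one transitional round)
            log.info("retry %d: reverting to the best state", retries)
            current, report = best_mesh, best_report
            prev_score = _score(best_report)
            stalled = True

    after = report
    log.info("pipeline done: theta_min=%.2f theta_max=%.2f pct<30=%.3f "
             "intersections=%s", after.theta_min, after.theta_max,
             after.pct_below_30, after.n_self_intersecting_pairs)
    return current, before, after
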
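# arthropose

Simulation-free repositioning of finite-element human body models.

Skeletons are reconfigured along geometry-derived joint trajectories —
notably a tibiofemoral flexion trajectory built by iterating contact search,
curvature-tensor–based instantaneous-helical-axis optimization, and
incremental rigid rotation — and soft tissues are adapted with thin-plate-
spline morphing, a morph–contact algorithm for the sliding joint-capsule
interface (penetration detection via signed distance and orientation flips,
outward patch pulling, optimization-based interface refinement), and an FE
hexahedral mesh-quality audit (scaled Jacobian, warpage, aspect ratio).

No licensed body model is required: `arthropose.synthetic_fixtures`
generates analytic knee geometries (sphere / cylinder / ellipsoid condyles
with known curvature and axis truth), a tube capsule around two bone
cylinders, and a toy limb FE model that exercise every pipeline stage.

## Layout

| module | role |
| --- | --- |
| `fe_model_io` | LS-DYNA keyword subset IO (`*NODE`, `*ELEMENT_SOLID/_SHELL`, `*PART`, `*SET_NODE…`), boundary-surface extraction |
| `surface` | triangle-mesh type, OBJ/STL/PLY ascii IO |
| `geometry_core` | normal-cycle curvature tensors, normal curvature, sphere/cylinder/plane fits, Rodrigues & intrinsic Euler rotations |
| `knee_trajectory` | contact search → helical-axis solve → incremental flexion trajectory |
| `joint_library` | ball/hinge/knee/spine joint definitions, kinematic-chain skeleton reconfiguration |
| `tps_morph` | thin-plate-spline landmark interpolation (3D kernel φ(r)=r) |
| `morph_contact` | capsule segmentation, preliminary morph, penetration detect/resolve, interface refinement, flesh TPS |
| `mesh_quality` | scaled Jacobian / warpage / aspect-ratio metrics and threshold audits |
| `synthetic_fixtures` | analytic fixtures with ground truth |
| `toolbox` | full pipeline orchestration |
| `cli` | `arthropose` command-line interface |

## CLI

```bash
# write a synthetic fixture (keyword model + OBJ surfaces + truth JSON)
arthropose fixture --kind toy_limb --out fixtures/ --seed 0

# reposition a model from a pose-parameter file (degrees)
arthropose reposition --model fixtures/toy_limb.k \
    --joints fixtures/joints.yaml --pose pose.json \
    --out posed.k --report report.json --step 0.5 --seed 0

# knee flexion trajectory from standalone condyle surfaces
arthropose knee-traj --medial m.obj --lateral l.obj \
    --plateau-medial pm.json --plateau-lateral pl.json \
    --target 40 --step 0.5 --out traj.json

# element-quality audit
arthropose quality --model posed.k --warpage 15 --aspect 5 --jacobian 0.5 \
    --out report.json
```

Pose files are JSON mapping joint names to degrees: a scalar for knee/elbow
flexion, three intrinsic angles `[internal_external, flexion_extension,
adduction_abduction]` or a 3×3 matrix for ball joints, a scalar (flexion)
or three angles for spine joints.  Exit codes: 0 success, 2 validation
failure, 3 non-convergence, 4 I/O error.

## Units & conventions

Millimetres and degrees at every public interface.  FE node ids are
1-based; mesh vertex indices 0-based, bridged by `source_node_ids`.
Capsule surfaces are oriented with outward normals toward the joint
interior (they bound the surrounding flesh).
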
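# molcage

Conservative geometric verification and high-throughput screening of
**molecular caging complexes** — host–guest pairs in which a cage-like host
molecule encloses a guest so that no collision-free rigid motion lets the
guest escape. Caging is a purely geometric, shape-based property (distinct
from binding affinity) with applications in targeted delivery, molecular
shape sorting and virus trapping; the practical bottleneck is finding
candidate host–guest pairs, which calls for computational pre-screening.

`molcage` is for computational chemists who want to screen candidate hosts
against candidate guests (or conformational ensembles of either) *before*
synthesis, with a mathematical guarantee attached to every positive
prediction.

## The model and the guarantee

Each molecule is a hard-sphere model: a union of balls at the atomic
coordinates with van der Waals radii r_i (Bondi-style defaults,
user-overridable). A guest *configuration* is a rigid placement
(t, q) ∈ SE(3): a translation t of its reference point plus a rotation q.
Its **free space** F ⊂ SE(3) is the set of placements where no guest ball
overlaps a host ball. If F contains a **bounded connected component** — a
finite-extent region not connected to infinity — the guest provably cannot
escape: the pair is a caging complex.

`molcage` discretizes SE(3) as a translation grid (cell edge h) × a
quasi-uniform rotation sample set (covering radius θ_cov) and labels a cell
`BLOCKED_CERTAIN` only when the deepest sphere overlap at the cell-center
placement exceeds the Lipschitz displacement margin

    m = (√3/2)·h + 2·ρ·sin(θ_cov/2),

where ρ is the guest circumradius — so *every* placement the cell covers is
provably in collision. Everything else stays `FREE_POSSIBLE`; the labeled
map therefore **over-approximates** the true free space. A flood fill from
the grid boundary marks every escape-reachable free cell; a strictly
collision-free placement in an unreached free region is a **witness** that
the guest is caged (`PROVEN_CAGED`). The guarantee is one-sided:
`NOT_PROVEN` never certifies escapability.

Geometric uncertainty is handled by re-running verification with all radii
of both molecules shifted by −Δr, 0, +Δr (default Δr = 0.3 Å):

* **strong** — proven caged at every offset,
* **weak** — the verdict flips under the shifts,
* **not** — never proven caged.

## Worked example

```python
from molcage.fixtures import make_shell_cage, make_guest_ball
from molcage.robustness import classify_pair, RobustnessParams
from molcage.cspace import VerifyParams

# a sealed shell cage: cavity clearance 3.0 A, no straight exit ray
host, spec = make_shell_cage(4.0, 1.0, 100, target_passage=0.5)
print(f"cavity {spec.cavity_clearance:.1f} A, passage bound {spec.passage_bound:.3f} A")

guest = make_guest_ball(1.2)
result = classify_pair(host, guest, RobustnessParams(0.3, VerifyParams(h=0.5)))
print("class:", result.value)
for off, v in result.per_offset:
    print(f"  delta_r {off:+.1f} A: {v.outcome} ({v.diagnostic})")
```

prints

```
cavity 3.0 A, passage bound -0.015 A
class: strong
  delta_r -0.3 A: PROVEN_CAGED (witness_found)
  delta_r +0.0 A: PROVEN_CAGED (witness_found)
  delta_r +0.3 A: PROVEN_CAGED (witness_found)
```

The negative passage bound says not even a point can leave the cavity along
a straight ray; the 1.2 Å ball guest fits the 3.0 Å cavity with room to
spare at every radius offset, so the pair is a *strong* caging complex —
each `PROVEN_CAGED` line is backed by an explicit witness placement in a
free region the exterior flood fill cannot reach.

From the shell, screening works on plain coordinate files:

```
molcage screen --hosts hosts/ --guests guests/ --delta-r 0.3 \
    --out matrix.csv --detail-out details.json
molcage summarize --matrix matrix.csv --axis hosts
```

`matrix.csv` holds one row per host, one column per guest, each cell
`strong`, `weak` or `not`. Inputs may be xyz, pdb or mol2; a conformational
ensemble is just a directory with one file per conformation.

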
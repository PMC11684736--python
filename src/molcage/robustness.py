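"""Radius-perturbation robustness: the strong / weak / not classification.

Uncertainty in the hard-sphere geometry is modeled by re-running caging
verification with all atomic radii of both molecules jointly shifted by
each offset in {-delta_r, 0, +delta_r} (default delta_r = 0.3 A). A pair
is a *strong* caging complex when every offset is proven caged, *not* a
caging complex when no offset is, and *weak* otherwise — the verdict flips
under small size changes, either because the inflated guest no longer fits
or because the deflated one can escape.

Strong/weak caging is a purely geometric robustness notion; it carries no
binding-affinity meaning. Choosing delta_r is a modeling decision left to
the user (0.3 A is a reasonable default; comparing against smaller values
is encouraged); delta_r = 0 degenerates to a single non-robust verification
and is flagged as such in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cspace import CagingVerdict, VerifyParams, verify_caging
from .geometry import GeometryError, SphereSet, perturb_radii

__all__ = [
    "RobustnessParams",
    "RobustnessClass",
    "validate_delta_r",
    "classify_pair",
]


@dataclass(frozen=True)
class RobustnessParams:
    """delta_r sweep plus the verification resolution forwarded per offset."""

    delta_r: float = 0.3
    verify: VerifyParams = field(default_factory=VerifyParams)

    @property
    def offsets(self) -> tuple[float, ...]:
        if self.delta_r == 0:
            return (0.0,)
        return (-self.delta_r, 0.0, self.delta_r)


@dataclass(frozen=True)
class RobustnessClass:
    """strong | weak | not, with the per-offset verdicts retained."""

    value: str
    per_offset: tuple[tuple[float, CagingVerdict], ...]

    @property
    def verdicts(self) -> dict[float, CagingVerdict]:
        return dict(self.per_offset)


def aggregate(caged_flags) -> str:
    """Pure classification from the per-offset caged/not-caged multiset:
    strong = all caged, not = none caged, weak = mixed."""
    flags = list(caged_flags)
    if not flags:
        raise ValueError("no per-offset verdicts to aggregate")
    if all(flags):
        return "strong"
    if not any(flags):
        return "not"
    return "weak"


def validate_delta_r(host: SphereSet, guest: SphereSet, delta_r: float,
                     verify: VerifyParams | None = None) -> RobustnessParams:
    """Check that the -delta_r offset keeps every atomic radius positive and
    return populated sweep parameters."""
    if delta_r < 0:
        raise GeometryError("delta_r must be non-negative")
    for name, mol in (("host", host), ("guest", guest)):
        i = int(np.argmin(mol.radii))
        if mol.radii[i] <= delta_r:
            raise GeometryError(
                f"delta_r={delta_r:g} A is not below the smallest atomic radius of the "
                f"{name} (atom {i}, {mol.elements[i]}, r={mol.radii[i]:g} A)"
            )
    return RobustnessParams(delta_r=float(delta_r), verify=verify or VerifyParams())


def classify_pair(
    host: SphereSet, guest: SphereSet, params: RobustnessParams | None = None
) -> RobustnessClass:
    """Run verification once per radius offset (both molecules perturbed
    jointly) and classify the pair. Radius underflow at -delta_r is raised
    before any verification runs."""
    params = params or RobustnessParams()
    params = validate_delta_r(host, guest, params.delta_r, params.verify)
    results = []
    for off in params.offsets:
        verdict = verify_caging(
            perturb_radii(host, off), perturb_radii(guest, off), params.verify
        )
        results.append((off, verdict))
    value = aggregate(v.caged for _, v in results)
    return RobustnessClass(value=value, per_offset=tuple(results))
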
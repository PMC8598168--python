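"""Enumerate the combinatorial stimulus space and build its design matrix.

Five stimulus elements (whiskers C2, C1, B1, D1, gamma) give 31 non-empty
combinations plus a no-stimulus catch condition.
"""

import combicode as cc

space = cc.enumerate_conditions(5, include_catch=True)
print(f"{len(space.non_catch)} stimulus conditions "
      f"({len(space.singletons)} single-element, {len(space.multis)} multi-element), "
      f"{len(space.conditions)} including catch")

print("first six in canonical order:", ", ".join(space.labels()[:6]))

X = cc.design_matrix(space)
print(f"design matrix: {X.shape[0]} conditions x {X.shape[1]} elements, "
      f"{X.sum()} ones total")
# row i marks which elements are present in condition i; it is the x_ij
# regressor matrix used by the linear-nonlinear model and the per-element fit
full = space.non_catch[-1]
print("row for the full combination:", X[space.non_catch.index(full)])
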
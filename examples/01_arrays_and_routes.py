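"""Arrays, route distances and optimal open paths.

Builds the three experimental array fixtures, prints their pairwise
geometry and the brute-force optimal open (Hamiltonian) path — the shortest
way to visit every platform once without returning to the start.
"""

import trapline as tl

for name in tl.ARRAY_NAMES:
    arr = tl.get_array(name)
    opt = tl.optimal_open_path(arr)
    print(f"{name}: {arr.n} platforms, {tl.count_routes(arr.n)} possible routes")
    print(f"  optimal open path {'-'.join(opt.sequence)}  length {opt.length:.2f}")
    print(f"  intercept prior centre log(2*L_min) = {tl.prior_center(arr):.3f}")

# a route with a revisit pays for every transition it makes
dt = tl.get_array("double_trapezoid")
seq = ["1", "2", "3", "2", "4", "5", "6"]
print(
    f"\nroute {'-'.join(seq)} on the double trapezoid travels "
    f"{tl.route_distance(dt, seq):.2f} "
    f"(optimum {tl.optimal_open_path(dt).length:.2f})"
)
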
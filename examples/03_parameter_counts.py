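"""Parameter accounting: pseudo-3D factorization versus dense 3D convolution.

A dense n x n x n kernel costs n^3 weights; the factorized pair (one
in-plane n x n x 1 kernel, one through-plane 1 x 1 x n kernel) costs
n^2 + n.  The reduction carries through to whole networks.
"""

from cephalo3d import NetworkSpec, P3DBlockSpec, build_network, count_parameters
from cephalo3d.network import build_pa_p3d_block

for n in (3, 5, 7):
    lean = P3DBlockSpec(1, 1, kernel=n, attention="none", norm=False, bias=False)
    fact = count_parameters(build_pa_p3d_block(lean))
    dense = count_parameters(build_pa_p3d_block(lean, dense=True))
    print(f"n={n}: factorized {fact:4d} (= n^2+n) vs dense {dense:4d} (= n^3)")

spec = NetworkSpec(landmarks=14, depth=3, base_channels=8, crop=(48, 48, 40))
dense_spec = NetworkSpec(landmarks=14, depth=3, base_channels=8,
                         crop=(48, 48, 40), dense=True)
pa = count_parameters(build_network(spec))
dn = count_parameters(build_network(dense_spec))
print(f"\ntiny preset U-Net: PA-P3D {pa:,} vs dense-conv {dn:,} parameters "
      f"({100 * (1 - pa / dn):.0f}% fewer)")
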
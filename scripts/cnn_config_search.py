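#!/usr/bin/env python
"""Exhaustive search for CNN configurations with a given parameter total.

The published parameter total (75106) does not pin down the convolutional
hyperparameters.  This script enumerates kernel sizes {3,5} per axis, filter
counts 4..64, same/valid convolution padding, and floor/ceil 2x2/stride-2
pooling — constrained to two conv/pool blocks followed by dense(128),
dense(64) and a 2-class head on a 22x20x7 input — and prints every
configuration whose trainable-parameter total matches exactly.

The configuration frozen in spectronet.nets.models (conv 3x5 x5 same ->
conv 3x3 x17 same, ceil pooling) is the hit with the fewest conv
multiply-accumulates.
"""

import argparse
import itertools


def conv_out(n: int, k: int, pad: str) -> int:
    return n if pad == "same" else n - k + 1


def pool_out(n: int, mode: str) -> int:
    return (n + 1) // 2 if mode == "ceil" else n // 2


def conv_macs(h, w, k1, k2, cin, cout, pad):
    oh, ow = conv_out(h, k1, pad), conv_out(w, k2, pad)
    return oh * ow * k1 * k2 * cin * cout


def search(total: int, h: int = 22, w: int = 20, c: int = 7,
           dense=(128, 64), n_classes: int = 2):
    hits = []
    head = dense[0] * dense[1] + dense[1] + dense[1] * n_classes + n_classes
    for kh1, kw1, kh2, kw2 in itertools.product([3, 5], repeat=4):
        for pad1, pad2 in itertools.product(["same", "valid"], repeat=2):
            for pool in ["floor", "ceil"]:
                h1 = pool_out(conv_out(h, kh1, pad1), pool)
                w1 = pool_out(conv_out(w, kw1, pad1), pool)
                if h1 < 1 or w1 < 1:
                    continue
                for c1 in range(4, 65):
                    p1 = kh1 * kw1 * c * c1 + c1
                    for c2 in range(4, 65):
                        h2 = pool_out(conv_out(h1, kh2, pad2), pool)
                        w2 = pool_out(conv_out(w1, kw2, pad2), pool)
                        if h2 < 1 or w2 < 1:
                            continue
                        p2 = kh2 * kw2 * c1 * c2 + c2
                        flat = h2 * w2 * c2
                        count = p1 + p2 + flat * dense[0] + dense[0] + head
                        if count == total:
                            macs = conv_macs(h, w, kh1, kw1, c, c1, pad1) \
                                + conv_macs(h1, w1, kh2, kw2, c1, c2, pad2)
                            hits.append((macs, (kh1, kw1, c1, pad1),
                                         (kh2, kw2, c2, pad2), pool, flat))
    return sorted(hits)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--total", type=int, default=75106)
    args = parser.parse_args()
    hits = search(args.total)
    for macs, b1, b2, pool, flat in hits:
        print(f"conv1={b1} conv2={b2} pool={pool} flat={flat} "
              f"conv_macs={macs}")
    print(f"{len(hits)} configuration(s) with exactly {args.total} parameters")


if __name__ == "__main__":
    main()
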
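import numpy as np
import pandas as pd
import pytest

from methylgxe import DataError, find_vml, summarize_all, summarize_vmr
from methylgxe.vml_identification import vml_to_bed

from conftest import make_manifest


def _meth(n, cols):
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])


def _correlated(rng, n, r):
    a = rng.standard_normal(n)
    b = r * a + np.sqrt(1 - r**2) * rng.standard_normal(n)
    return a, b


def test_chain_and_sparse_rules(rng):
    """A+B chain into a VMR (gap 800 < 1 kb, r > 0.15); C with its nearest
    manifest probe 1,200 bp away becomes a sVMP."""
    n = 100
    a, b = _correlated(rng, n, 0.5)
    c = rng.standard_normal(n)
    meth = _meth(n, {"A": a, "B": b, "C": c})
    manifest = make_manifest(
        "probe",
        [("A", "chr1", 1000), ("B", "chr1", 1800), ("C", "chr1", 3000),
         ("D", "chr1", 4200)],  # D: non-HVP neighbour 1,200 bp from C
    )
    vmls = find_vml(["A", "B", "C"], manifest, meth)
    kinds = {v.vml_id: v for v in vmls}
    assert len(vmls) == 2
    vmr = next(v for v in vmls if v.kind == "VMR")
    svmp = next(v for v in vmls if v.kind == "sVMP")
    assert vmr.probe_ids == ["A", "B"] and (vmr.start, vmr.end) == (1000, 1800)
    assert svmp.probe_ids == ["C"] and svmp.vml_id == "chr1:3000-3000(sVMP)"


def test_uncorrelated_neighbours_are_discarded(rng):
    """Probes < 1 kb apart but with r <= 0.15 form no VMR, and their mutual
    proximity also disqualifies them as sVMPs."""
    n = 200
    a, b = _correlated(rng, n, 0.05)
    meth = _meth(n, {"A": a, "B": b})
    manifest = make_manifest("probe", [("A", "chr1", 1000), ("B", "chr1", 1800)])
    assert find_vml(["A", "B"], manifest, meth) == []
    # under svmp_mode="hvp" the outcome is the same (they are each other's
    # neighbours); with distant positions both become sVMPs
    manifest_far = make_manifest("probe", [("A", "chr1", 1000), ("B", "chr1", 98000)])
    vmls = find_vml(["A", "B"], manifest_far, meth)
    assert [v.kind for v in vmls] == ["sVMP", "sVMP"]


def test_lone_probe_summary_is_its_own_column(rng):
    n = 50
    meth = _meth(n, {"A": rng.standard_normal(n)})
    manifest = make_manifest("probe", [("A", "chr9", 777)])
    (vml,) = find_vml(["A"], manifest, meth)
    assert vml.kind == "sVMP"
    summary = summarize_all(meth, [vml])
    np.testing.assert_array_equal(summary[vml.vml_id].to_numpy(), meth["A"].to_numpy())


def test_missing_coordinates_fatal(rng):
    meth = _meth(10, {"A": rng.standard_normal(10)})
    manifest = make_manifest("probe", [("Z", "chr1", 10)])
    with pytest.raises(DataError, match="coordinates"):
        find_vml(["A"], manifest, meth)


def test_median_summary_examples_and_oracle(rng):
    meth = _meth(1, {"p1": [1.0], "p2": [3.0]})
    assert summarize_vmr(meth, ["p1", "p2"]).iloc[0] == 2.0
    meth3 = _meth(1, {"p1": [-1.0], "p2": [0.0], "p3": [5.0]})
    assert summarize_vmr(meth3, ["p1", "p2", "p3"]).iloc[0] == 0.0
    # 30-probe region against an independent sort-based median
    big = _meth(40, {f"p{j}": rng.standard_normal(40) for j in range(30)})
    got = summarize_vmr(big, list(big.columns))
    arr = big.to_numpy()
    expected = np.sort(arr, axis=1)[:, 14:16].mean(axis=1)
    np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-12)
    with pytest.raises(DataError):
        summarize_vmr(big, ["p0"])
    with pytest.raises(DataError, match="missing"):
        summarize_vmr(big, ["p0", "nope"])


def _random_case(rng, n_probes=120, n=80):
    chroms = rng.choice(["chr1", "chr2"], n_probes)
    pos = np.sort(rng.integers(1, 60_000, n_probes))
    ids = [f"cg{j:03d}" for j in range(n_probes)]
    manifest = make_manifest("probe", list(zip(ids, chroms, pos)))
    meth = _meth(n, {i: rng.standard_normal(n) for i in ids})
    hvps = list(rng.choice(ids, size=60, replace=False))
    return hvps, manifest, meth


def test_partition_property(rng):
    """Every HVP lands in exactly one VML or is discarded."""
    hvps, manifest, meth = _random_case(rng)
    vmls = find_vml(hvps, manifest, meth)
    seen = [p for v in vmls for p in v.probe_ids]
    assert len(seen) == len(set(seen))
    assert set(seen) <= set(hvps)
    n_discarded = len(hvps) - len(seen)
    assert n_discarded >= 0


def test_translation_invariance(rng):
    hvps, manifest, meth = _random_case(rng)
    shifted = manifest.assign(pos=manifest["pos"] + 10_000)
    a = find_vml(hvps, manifest, meth)
    b = find_vml(hvps, shifted, meth)
    assert [(v.kind, v.probe_ids) for v in a] == [(v.kind, v.probe_ids) for v in b]
    assert all(bv.start == av.start + 10_000 for av, bv in zip(a, b))


def test_distance_only_chaining_matches_interval_merge_oracle(rng):
    """With the correlation test disabled (min_r=-1), VMRs are exactly the
    maximal < 1 kb distance chains."""
    hvps, manifest, meth = _random_case(rng)
    vmls = find_vml(hvps, manifest, meth, min_r=-1.0)
    got = sorted(
        tuple(v.probe_ids) for v in vmls if v.kind == "VMR"
    )
    # oracle: brute-force scan of sorted HVP positions
    man = manifest.set_index("probe_id")
    by_chrom = {}
    for p in hvps:
        by_chrom.setdefault(man.loc[p, "chrom"], []).append((man.loc[p, "pos"], p))
    expected = []
    for chrom in by_chrom:
        items = sorted(by_chrom[chrom])
        run = [items[0]]
        for prev, cur in zip(items, items[1:]):
            if cur[0] - prev[0] < 1000:
                run.append(cur)
            else:
                if len(run) >= 2:
                    expected.append(tuple(p for _, p in run))
                run = [cur]
        if len(run) >= 2:
            expected.append(tuple(p for _, p in run))
    assert got == sorted(expected)


def test_bed_export_is_zero_based_half_open(rng):
    n = 60
    a, b = _correlated(rng, n, 0.9)
    meth = _meth(n, {"A": a, "B": b})
    manifest = make_manifest("probe", [("A", "chr1", 1000), ("B", "chr1", 1500)])
    vmls = find_vml(["A", "B"], manifest, meth)
    bed = vml_to_bed(vmls)
    assert list(bed.iloc[0, :3]) == ["chr1", 999, 1500]
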
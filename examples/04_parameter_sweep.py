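"""Choose M and B by saturation, the way the defaults were picked.

For the first-stage size M: how many distinct positive marker groups are
represented in the top-M mRMR candidates?  For the bootstrap count B: how
many distinct features ever appear in a bootstrap top-M' list?  Both
curves plateau; the defaults (M=50, B=40) sit at the elbow for the
normal benchmark.
"""

from metaboot import MetaBootParams, generate_s1, sweep_parameters

dataset = generate_s1(sd=1.0, seed=3)
curves = sweep_parameters(
    dataset.table,
    dataset.metadata,
    M_grid=[10, 20, 50, 100],
    B_grid=[5, 10, 20, 40, 60],
    params=MetaBootParams(M=50, B=60, m_prime=10, seed=3),
    truth=dataset.truth,
)

print("M -> distinct positive groups in the first-stage top-M")
for m, count in curves["M"].items():
    print(f"  M={m:4d}: {count}")
print("B -> distinct features seen across bootstrap top-10 lists")
for b, count in curves["B"].items():
    print(f"  B={b:4d}: {count}")
# Once the M-curve reaches 10 (all groups) and the B-curve stops growing,
# larger values only cost time.
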
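"""Test whether two pathways combine linearly: combination versus the sum
of single-pathway responses, by two-way ANCOVA.

The cAMP→GEF branch and the Giβγ branch both load the same inactive
GTPase pool, so driving them together yields less ppERK than the sum of
the separate responses — sublinear summation by substrate competition.
"""

from synerk import ExperimentPlan, build_fixture_network, run_combination_suite

net = build_fixture_network()
res = run_combination_suite(
    net, {"cAMP": 500.0, "Gbg": 100.0}, [1, 4, 10, 30, 100], "duration",
    plan=ExperimentPlan(name="combo", method="ode", post_window=600.0),
)
print(res.table[["x", "auc_combo", "auc_sum"]].round(0).to_string(index=False))
a = res.ancova
print(f"\nANCOVA: F = {a.f_stat:.1f}, df = {a.df}")
print(f"  stimulation (duration): t = {a.t_stim:.2f}, p = {a.p_stim:.2g}")
print(f"  type (combo vs sum):    t = {a.t_type:.2f}, p = {a.p_type:.2g}")
print(f"verdict: {a.verdict}")
print("(a significant negative type effect means the combined response "
      "falls short of additivity: both branches compete for the GTPase pool)")
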
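"""Sex-specific and sex-overlapped networks from the two sex networks.

Patterns are matched by their disease-pair identity: the overlapped
network is the edge intersection of the male and female complete
networks, a sex-specific network the edge difference.  The decomposition
identity |complete| = |specific| + |overlapped| holds by construction.
"""

from multimorbnet import (
    build_network,
    generate_records,
    overlapped,
    prepare_strata,
    specific,
)
from multimorbnet.simulate import decomposition_config

records, truth = generate_records(decomposition_config(seed=17, n_per_sex=10_000))
strata = prepare_strata(records, scheme="sex")
male = build_network(strata["male_40-59"])
female = build_network(strata["female_40-59"])

shared = overlapped(male, female)
male_spec = specific(male, female)
female_spec = specific(female, male)

print(f"male complete   : {male.n_edges} patterns across {male.n_nodes} diseases")
print(f"female complete : {female.n_edges} patterns across {female.n_nodes} diseases")
print(f"overlapped      : {shared.n_edges} patterns across {shared.n_nodes} diseases")
print(f"male-specific   : {male_spec.n_edges} patterns")
print(f"female-specific : {female_spec.n_edges} patterns")
print(f"identity male   : {male.n_edges} = {male_spec.n_edges} + {shared.n_edges}")
print(f"identity female : {female.n_edges} = {female_spec.n_edges} + {shared.n_edges}")

male_only = {k for k, v in truth.planted["male_40-59"].items() if v["scope"] == "male_only"}
in_spec = male_only & {"|".join(e.key) for e in male_spec.edges}
print(f"male-only planted pairs found in the male-specific network: "
      f"{len(in_spec)}/{len(male_only)}")
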
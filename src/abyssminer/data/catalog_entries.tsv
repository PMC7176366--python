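label	role_class	source_cluster	mobile_element	min_identity	min_coverage
abyU	diels_alderase	aby	0	0.3	0.5
abyA1	tetronate	aby	0	0.3	0.5
abyA2	tetronate	aby	0	0.3	0.5
abyA3	tetronate	aby	0	0.3	0.5
abyA4	tetronate	aby	0	0.3	0.5
abyA5	tetronate	aby	0	0.3	0.5
abyB1	PKS	aby	0	0.3	0.5
abyB2	PKS	aby	0	0.3	0.5
abyB3	PKS	aby	0	0.3	0.5
abyC	regulator	aby	0	0.3	0.5
abyD	transport	aby	0	0.3	0.5
abyE	tailoring	aby	0	0.3	0.5
abyF1	transport	aby	0	0.3	0.5
abyF2	transport	aby	0	0.3	0.5
abyF3	transport	aby	0	0.3	0.5
abyF4	transport	aby	0	0.3	0.5
abyH	regulator	aby	0	0.3	0.5
abyI	regulator	aby	0	0.3	0.5
abyK	other	aby	0	0.3	0.5
abyM	other	aby	0	0.3	0.5
abyN	other	aby	0	0.3	0.5
abyR	regulator	aby	0	0.3	0.5
abyT	tailoring	aby	0	0.3	0.5
abyV	tailoring	aby	0	0.3	0.5
abyW	tailoring	aby	0	0.3	0.5
abyX	tailoring	aby	0	0.3	0.5
abyZ	tailoring	aby	0	0.3	0.5
absU	diels_alderase	abs	0	0.3	0.5
absC1	regulator	abs	0	0.3	0.5
absC2	regulator	abs	0	0.3	0.5
absG1	tailoring	abs	0	0.3	0.5
absG2	tailoring	abs	0	0.3	0.5
absI	tailoring	abs	0	0.3	0.5
absJ	tailoring	abs	0	0.3	0.5
abmU	diels_alderase	abm	0	0.3	0.5
abmK	tailoring	abm	0	0.3	0.5
abmL	tailoring	abm	0	0.3	0.5
abmM	tailoring	abm	0	0.3	0.5
abmN	tailoring	abm	0	0.3	0.5
abmE2	tailoring	abm	0	0.3	0.5
abmJ	tailoring	abm	0	0.3	0.5
abmG	tailoring	abm	0	0.3	0.5
transposase	other	none	1	0.3	0.5
integrase	other	none	1	0.3	0.5
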
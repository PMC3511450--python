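# Ten-reaction toy signalling model: 2 stimuli (TGFa, TNFa), 2 explicit
# inhibitor nodes (MEK12i, PI3Ki), 1 latent node (PI3K) and 5 measured
# signals (MEK12, ERK12, AKT, JNK, P38). Four AND gates (each carrying a
# NOT input from an inhibitor node) and four OR gates (PI3K, MEK12, JNK
# and P38 each have two producing reactions).
#
# The two PI3K-producing gates (and1, and2) place the PI3Ki NOT input on
# PI3K's producing reactions; this wiring is inferred from the model's
# described behaviour (PI3Ki abolishes AKT activation under either
# stimulus) rather than from an explicit reaction list, and is the single
# point to edit if a different PI3Ki placement is preferred.
TNFa	1	JNK
PI3K	1	JNK
TNFa	1	P38
PI3K	1	P38
MEK12	1	ERK12
PI3K	1	AKT
TGFa	1	and1
PI3Ki	-1	and1
and1	1	PI3K
TNFa	1	and2
PI3Ki	-1	and2
and2	1	PI3K
TGFa	1	and3
MEK12i	-1	and3
and3	1	MEK12
PI3K	1	and4
MEK12i	-1	and4
and4	1	MEK12
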
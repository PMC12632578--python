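# Example montage config: the 14-channel longitudinal bipolar montage over a
# recording whose channels are already named by 10-20 labels (as produced by
# `neosleep simulate --eeg`).  For high-density nets, replace the MAP indices
# with the source-channel index of each 10-20-equivalent electrode in your
# layout (consult the vendor's position document for your net revision).
PAIR Fp1 T3
PAIR T3 O1
PAIR Fp2 T4
PAIR T4 O2
PAIR Fp1 C3
PAIR C3 O1
PAIR Fp2 C4
PAIR C4 O2
PAIR T3 C3
PAIR C3 Cz
PAIR Cz C4
PAIR C4 T4
PAIR Fz Cz
PAIR Cz Pz
MAP Fp1 0
MAP Fp2 1
MAP C3 2
MAP C4 3
MAP Cz 4
MAP T3 5
MAP T4 6
MAP O1 7
MAP O2 8
MAP Fz 9
MAP Pz 10
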
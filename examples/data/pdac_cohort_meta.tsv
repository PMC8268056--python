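sample_id	group	subject_label	paired_with
T1	tumor	PAT01	N1
T2	tumor	PAT02	N2
T3	tumor	PAT03	N3
N1	adjacent_normal	PAT01	T1
N2	adjacent_normal	PAT02	T2
N3	adjacent_normal	PAT03	T3
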
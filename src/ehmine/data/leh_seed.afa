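>seed1
HWQIDSINPGIWSGDICYQFTTHQDLNASVRNYIKILQLHPMCIHCAGFTVTYQNLKKLTIFVNNYCSFITLEMSWWRSIFLECGLPFCCYCHFAQAERNDPHYRLKSAAAPKLPIWWGEDQCAHEFDVWEDCQWPFGWMCLMYVLGRW
>seed2
HWQIDSINPGIWSVDICYQFTTHHDLDASVRNYIKILQLHPMCIHCAGFTVTYQNLKYLTIFVNNYCSFITLEMSWCRSIFLECGLPFGCLCHTAQQERNDPHYRLKIAAAPKLPIWWGEDQCAHCFDVWEDCQWPFGWMCLMYVLGRW
>seed3
HWQIDSINPGKWSVDICYQFTTHQDLNASVRNYIKILQLHPMCIHCAGFTVYYQNLKYLTIFVNPYCSCITLEMSWCRSIFLECGLPFGCVCHFAQAFRNDPHYRLKSAAAPKLPIWWGEEQCAHCFDVWEDCQWPFGWMCLMYVLGRW
>seed4
HWQIDSINPIIWSVDICYQFTTHQDLNASVRNYIKILQLEPMCIHCAGFTVTYQNLKYLTIFVNNYCSFITLEMSWCRSIFPESGLPFGELCHFAQAERNDPRFRLKSAAAPKLPIWWNYDQCAHCHDVWNDCQMPFGWMCLMYVLGRW
>seed5
HWKINCINIGINSVDICYYFTAHGVLLARTYTYLKLLQLNSLCIHCAGFHHTYQNLKYLTIFVNNYCSFITLEMASWRSIRLEYGLMFHCACHDAQAERNDPWYRLKMAAAFFLPIWEGFDQIYHNFDVWEDCQKNFAPVYLMYKLARW
>seed6
HWKINCINIGINSMDICYYFKTHGVLLASTYTYLKLLQLNSLCIHCAGFHHTYQNLKYLTIFVNNYCSDITLEMASWRSIGLECGLMDHCACHDAQAERNDPWYRLKMAAAPFLPIWWGFDNIYGNFDVWEDCQNWFAPVFLMYKLARW
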
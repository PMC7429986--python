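>seed1
KFVKLTGGRTYDPKVTLENHSHQFEWLNWTGMVFNGSWRFIACPDHWLGDQLEEIWWAFNHNWKTTLIARGTNVQNHWCTRNWARRSHYSRLTAIIADECTAIKNLDHVFDCKTVNVVNS
>seed2
KFVKLTGGSTYDPKVTLENHAIQFRWLNWTGMVFAGSWRFGACPDHWLGDQLEEIPWAFNHNWNTQGIARGTNVQNHWCTRNWARRSHYSRLTYSAADECTAIKNLDTVFDCKTVNVNNS
>seed3
KFVKDTGGSTYDPKVKLENHAHQFRWLNWTGMVFAHYWRFGACPDHWLGDQLEEIPWAFNHNWNTHGAARGTNVQNHWCTRNWAPLSLYSRLTFSAADECFAIKNGDHVFDCKTVNVANS
>seed4
KFVVLTGGMTYDPKVFMENHAHQFRWLNWTGMGFAGSWRFGACPDHMLGDQLEEIPWSFWHNWNTQGIARGTNVQNHWCTRNWVRRSHYSRLTASAADECTAIKNDDHVFDCKTVNVVNS
>seed5
KFVKLTGGSAKDPKVTLENHAHQFRWLNWTGMVFAGSWRFGACPDHWLGDQLELKPQAFNHNWNTQGIARGMNVQNHWKTRNWARRGIYSRLTASAADECTAIKNLDHVFDSKTVNVVNS
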
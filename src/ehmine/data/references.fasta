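>refG5a synthetic abEH reference scaffold
KFVILTGGDTYDPKVTLENHEHQFRWLNWTGMVFAGSWRFGAWPDHWLHDQLEEIPWAENHNWNTQGIARATNVQNHWCTRNWERRSHYSRLTASAADECTAIKNLDHVFDCKTVNVKNSGSSGWHNLSHRNDKCYWAVLRDHDYEKVITANKAIKAVGEVIIHGWPSSICHRHGYISCARNFYISRFCWIPLASAFIERWKMPYECPHDKIDRMKQPGDASEAAFYGYQDFEEQCNETCNMCQFWQWHLTRVWWGQLYVLAYQLTMMMYGQCVCNQWYNRSGEMPTHADLYKIPASDERWFYRWDKVMNPDEPFCCEKPDPKEWDDQHMTNNSYKTSNLVHYNTNECGPVPTDYELKDWAMNPCIVWCLVSGPWPYFICTTFIWRAMTCVVKQGHILHNVTEHSSAHVMVRHKIWWWVSGFWH
>refG5b synthetic abEH reference scaffold
KFVKLTGGSTYDPKVTLENHAHQFRWLNWTGMVFAGSWRFGACPDHWLGDQLEEIPWAFNHNWNTQGIARGTDVQNHWCTRNWARRSHYSRLTASAAQECTAIKNCDHVFACITVNVVNSGSSGWHNLSHRNDKCIWAVLRDHLKEKVITANKAIKAKGEVIIHGWPSSICHRHGWISCARHHYISRFCWIPYASAFIERWKMPYECPHDKIKRMKQPGDASEMAFYGYQDFEEQCNKNCNMCQFWQWILTRVWWGQLYVLGYQLTMNMYGQWVCNCWYNRSGEMPTGADLYKTPASLERWFYRWDKVMFPDEPFCCFKPYEEEWDDQRFTNNSYKTSPLVHYNTNECNPVPTDYELKDWAMNPKIVWCLVSGPWPYFICTNEIMRGDTCGVKHGHIMHNVHEHGSAHVMVRGKIWWWVSGFWH
>refG8a synthetic abEH reference scaffold
EHKKGTFQDHHKGPKTWFGWVHGSQMWEKNLLQEDKLWAHGFPRFQRLRARNLGEMTIDKEWEWAELFEYHIVQWNVDLNVAWACAEMMCTAMCMMFPFFAWKEVTDWHPCFKENGQNWTSEFLEFESEEDECQYMDQEFHGDHEQFGGQGPHQYKMSFLGGGLMQMDMRRMHWKDIVREHDVLKAPLFDFQWSALQDRERYRMCKIKTSPEDEAFSVNRTWVWAYRHFPTVSTDAFYLKMFKGMWFHSKTDKLIPNLCHDNSIPTMHMLNLMYHEKTVSATSWCFYYGIYYWGDGHLWN
>refG8b synthetic abEH reference scaffold
AHKKGGSQDHHKGNKTWFWWVHGSQMWHKNLLQEDKLWRHGFPRFQLLRAFNLPEVTIDKEWEWAELFEYSNVQWNMDLNVAWACAEMMCRAYCMRFPFFAWKESKDWMPCFKEAGLNWTSEFLEDESEICECQYMAQEFHGDHETFGGQGPHQYKMSDLGGGLMQKDMRRMHWYTIVREHDVLKAPLFDFTWSQLQDRERYDMCHIKVSPEDEAFSYNRTWVWANRGFPTVNPDAFYLKMFKFMWFHIKTDSFIPNSCHYNSIPIMHHLNLMYHEKKVKATSWQFYMGVYYWGWGHLWN
>refG6dh synthetic dehalogenase reference scaffold
EHAKGTDQDHHKGVKTWFWGVHGSQMWHKVLLQEDKLWAHGNPRYQLLRARNTGEMTWDAEWEWAELVEYHNVQWNMDLHQAWAKAGNMCRNYEMNFACHAWKEMIDRLPRFPERNLNWEYEFKEFESEVCEGMYMAQEFHGDHEHFGGQGPHQYKMSFLRFGLMQMDMFRKHWKMIVCEHVDLKNPLYDSTWSGLQTRERLDMCHIKASPEDECFKVNRTWHAVNRGFPYVIDDAFYYPMFKGMWFHIWHDPLIPQLMHCSYIPIMHHGNLHYHEETVSTTSGQFYWGIDIWGWGHLWN
>refLEHa1 synthetic LEH reference scaffold
HWQIDSINPGSWSVDICYDFTTHQDAVAQVRNYIKILQLHPMNIHCEGFTVPYQNLKYLTIFVKNYCSFITLEMSWCRSIFLECGLPFGCLCHFAQKERNDPHYRQKSAAAPKLPIWWGEDQCDHCFDVWEDCQWPFGWMHLMKVLGRW
>refLEHa2 synthetic LEH reference scaffold
HWQPDSIMPGIWSVDICWQWTTHQDLNASVRNYIKILQLHTMCIHCAGKTVTYVNLKYLTIFVNNYCSFITLEMSWCRGIFLECGLPFCCFCHFAQAERNDPHYRLKSAAAPKLPIWWGEDQCAHCFAVWEDCQWPFAWGCLMYVDGRW
>refLEHb1 synthetic LEH reference scaffold
HWKINCINIGINSVDICEEFTYHGVLLASTYNYLKLLQLNSLCIHCAGFHHTYQNLKYLTIFVNNSCSFITLEMASWDSIFLEMGLMFHCICHDAQCERNDPWYRLKMKAAPFLPIWCGDDQIYHNFDVWEDCQNCFAPVYLMYKLATW
>refLEHb2 synthetic LEH reference scaffold
HWKINCINIGDNSVDICYYFTWHGVLLASTYTYLKLLQLNSLCIQCAGFHHTYQNLKYLTIFVNNYCTFITTTMASPRSIFLEMTLMFHCACHDAQAERNDAWYRNKMAAADFLPIWWGFDQIEHNFDVWEDCQNCFAPVYLMYTLARW
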
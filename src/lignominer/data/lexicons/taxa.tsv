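taxid	scientific_name	rank	common_names	synonyms	url
562	Escherichia coli	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=562
561	Escherichia	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=561
4932	Saccharomyces cerevisiae	species	baker's yeast|brewer's yeast		https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=4932
4930	Saccharomyces	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=4930
4922	Komagataella pastoris	species		Pichia pastoris	https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=4922
51453	Trichoderma reesei	species		Hypocrea jecorina	https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=51453
5543	Trichoderma	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5543
5061	Aspergillus niger	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5061
5059	Aspergillus flavus	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5059
746128	Aspergillus fumigatus	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=746128
5062	Aspergillus oryzae	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5062
5052	Aspergillus	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5052
5506	Gibberella	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5506
5518	Gibberella zeae	species		Fusarium graminearum	https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5518
5507	Fusarium oxysporum	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5507
5508	Fusarium	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5508
5306	Phanerochaete chrysosporium	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5306
5305	Phanerochaete	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5305
5141	Neurospora crassa	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5141
5140	Neurospora	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5140
5073	Penicillium	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5073
5076	Penicillium chrysogenum	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5076
85995	Humicola insolens	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=85995
5541	Thermomyces lanuginosus	species		Humicola lanuginosa	https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5541
78579	Myceliophthora thermophila	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=78579
68825	Talaromyces emersonii	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=68825
28556	Talaromyces	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=28556
5544	Trametes versicolor	species		Coriolus versicolor	https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5544
5545	Trametes	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5545
5346	Pleurotus ostreatus	species	oyster mushroom		https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5346
5320	Pleurotus	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5320
2261	Pyrococcus furiosus	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=2261
2260	Pyrococcus	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=2260
1423	Bacillus subtilis	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=1423
1386	Bacillus	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=1386
4565	Triticum aestivum	species	wheat		https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=4565
5270	Ustilago maydis	species	corn smut		https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5270
29875	Chaetomium thermophilum	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=29875
5149	Chaetomium	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=5149
27334	Penicillium expansum	species			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=27334
36050	Humicola	genus			https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=36050
9913	Bos taurus	species	cattle|bovine		https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=9913
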
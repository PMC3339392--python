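recommended_name	systematic_name	ec_number	synonyms	swissprot_ids	url
endoglucanase	4-beta-D-glucan 4-glucanohydrolase	3.2.1.4	endo-1,4-beta-glucanase|carboxymethyl cellulase|CMCase|endo-beta-1,4-glucanase|cellulase	P07981	https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.4
cellobiohydrolase	4-beta-D-glucan cellobiohydrolase	3.2.1.91	exoglucanase|exocellobiohydrolase|1,4-beta-cellobiosidase	P62694	https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.91
beta-glucosidase	beta-D-glucoside glucohydrolase	3.2.1.21	cellobiase|gentiobiase|amygdalase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.21
endo-1,4-beta-xylanase	4-beta-D-xylan xylanohydrolase	3.2.1.8	xylanase|endoxylanase|beta-1,4-xylanase	P36217	https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.8
beta-xylosidase	4-beta-D-xylan xylohydrolase	3.2.1.37	xylan 1,4-beta-xylosidase|exoxylanase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.37
alpha-galactosidase	alpha-D-galactoside galactohydrolase	3.2.1.22	melibiase|alpha-gal		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.22
beta-galactosidase	beta-D-galactoside galactohydrolase	3.2.1.23	lactase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.23
alpha-L-arabinofuranosidase	alpha-L-arabinofuranoside arabinofuranohydrolase	3.2.1.55	arabinosidase|arabinofuranosidase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.55
feruloyl esterase	feruloyl-ester hydrolase	3.1.1.73	ferulic acid esterase|cinnamoyl ester hydrolase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.1.1.73
acetylxylan esterase		3.1.1.72	acetyl xylan esterase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.1.1.72
laccase	benzenediol:oxygen oxidoreductase	1.10.3.2	urishiol oxidase|phenol oxidase		https://www.brenda-enzymes.org/enzyme.php?ecno=1.10.3.2
lignin peroxidase		1.11.1.14	ligninase|diarylpropane peroxidase		https://www.brenda-enzymes.org/enzyme.php?ecno=1.11.1.14
manganese peroxidase		1.11.1.13	Mn-dependent peroxidase		https://www.brenda-enzymes.org/enzyme.php?ecno=1.11.1.13
versatile peroxidase		1.11.1.16	hybrid peroxidase		https://www.brenda-enzymes.org/enzyme.php?ecno=1.11.1.16
triacylglycerol lipase	triacylglycerol acylhydrolase	3.1.1.3	lipase|tributyrase	P41365	https://www.brenda-enzymes.org/enzyme.php?ecno=3.1.1.3
cutinase	cutin hydrolase	3.1.1.74			https://www.brenda-enzymes.org/enzyme.php?ecno=3.1.1.74
alpha-amylase	4-alpha-D-glucan glucanohydrolase	3.2.1.1	glycogenase|endoamylase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.1
glucoamylase	4-alpha-D-glucan glucohydrolase	3.2.1.3	amyloglucosidase|gamma-amylase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.3
invertase	beta-fructofuranosidase	3.2.1.26	saccharase|beta-fructosidase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.26
polygalacturonase	poly(1,4-alpha-D-galacturonide) glycanohydrolase	3.2.1.15	pectinase|pectin depolymerase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.15
pectin lyase		4.2.2.10	pectolyase		https://www.brenda-enzymes.org/enzyme.php?ecno=4.2.2.10
endo-1,4-beta-mannanase	4-beta-D-mannan mannanohydrolase	3.2.1.78	mannanase|beta-mannanase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.78
chitinase		3.2.1.14	chitodextrinase|poly-beta-glucosaminidase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.14
cellobiose dehydrogenase	cellobiose:acceptor 1-oxidoreductase	1.1.99.18	CDH|cellobiose oxidase		https://www.brenda-enzymes.org/enzyme.php?ecno=1.1.99.18
glucose oxidase	beta-D-glucose:oxygen 1-oxidoreductase	1.1.3.4	notatin|GOD		https://www.brenda-enzymes.org/enzyme.php?ecno=1.1.3.4
catalase	hydrogen-peroxide:hydrogen-peroxide oxidoreductase	1.11.1.6			https://www.brenda-enzymes.org/enzyme.php?ecno=1.11.1.6
aryl-alcohol oxidase		1.1.3.7	veratryl alcohol oxidase		https://www.brenda-enzymes.org/enzyme.php?ecno=1.1.3.7
xyloglucanase		3.2.1.151	xyloglucan endohydrolase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.151
alpha-glucuronidase		3.2.1.139	alpha-glucosiduronase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.139
arabinanase		3.2.1.99	endo-arabinanase|endo-1,5-alpha-L-arabinanase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.99
lichenase		3.2.1.73	licheninase|beta-glucanase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.73
beta-mannosidase	beta-D-mannoside mannohydrolase	3.2.1.25	mannobiase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.25
alpha-L-rhamnosidase		3.2.1.40	rhamnosidase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.40
tannase	tannin acylhydrolase	3.1.1.20	tannin esterase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.1.1.20
phytase		3.1.3.8	3-phytase|myo-inositol hexaphosphate phosphohydrolase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.1.3.8
protease		3.4.21.112	proteinase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.4.21.112
trehalase	alpha,alpha-trehalose glucohydrolase	3.2.1.28			https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.28
inulinase		3.2.1.7	inulase|2,1-beta-D-fructan fructanohydrolase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.7
dextranase	6-alpha-D-glucan 6-glucanohydrolase	3.2.1.11			https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.11
pullulanase	pullulan 6-alpha-glucanohydrolase	3.2.1.41	limit dextrinase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.41
pyranose oxidase		1.1.3.10	glucose 2-oxidase		https://www.brenda-enzymes.org/enzyme.php?ecno=1.1.3.10
galactose oxidase		1.1.3.9			https://www.brenda-enzymes.org/enzyme.php?ecno=1.1.3.9
superoxide dismutase		1.15.1.1	SOD		https://www.brenda-enzymes.org/enzyme.php?ecno=1.15.1.1
glyoxal oxidase		1.2.3.15			https://www.brenda-enzymes.org/enzyme.php?ecno=1.2.3.15
esterase		3.1.1.1	carboxylesterase		https://www.brenda-enzymes.org/enzyme.php?ecno=3.1.1.1
xylosidase		3.2.1.37			https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.37
amylase		3.2.1.1			https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.1
glucanase		3.2.1.4			https://www.brenda-enzymes.org/enzyme.php?ecno=3.2.1.4
peroxidase		1.11.1.7			https://www.brenda-enzymes.org/enzyme.php?ecno=1.11.1.7
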
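trait	category
drought tolerance	A
heat tolerance	A
salt tolerance	A
cold tolerance	A
waterlogging tolerance	A
sclerotinia resistance	B
blackleg resistance	B
clubroot resistance	B
verticillium resistance	B
abscisic acid content	H
auxin content	H
cytokinin content	H
oil content	S
protein content	S
glucosinolate content	S
erucic acid content	S
linolenic acid content	S
oleic acid content	S
palmitic acid content	S
seed yield	Y
plant height	Y
branch number	Y
silique number	Y
seed weight	Y
seeds per silique	Y
flowering time	Y
maturity time	Y
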
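code,name,level,aliases,groups
NOR,Northland,3,North Land|Nordland,Boreal Belt
EAS,Eastmarch,3,East March,Boreal Belt
WES,Westmere,3,West Mere|Ouestmère,Boreal Belt
SOU,Southvale,3,South Vale,Austral Belt
CEN,Centralia,3,Central Plain,Midlands
HIG,Highcrag,3,High Crag|Hochfels,Midlands
LOW,Lowfen,3,Low Fen,Midlands
ISL,Isleholm,3,Isle Holm|Islandia=ISL+SKE,Austral Belt
SKE,Skerrygard,3,Skerry Gard,Austral Belt
DES,Dunewaste,3,Dune Waste|Désert=DES,Austral Belt
RIV,Riverrun,3,Río Corrido,Midlands
FRO,Frostholt,3,Frost Holt,Boreal Belt
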
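label,start,end
<1700,1600,1700
1700-1749,1700,1749
1750-1799,1750,1799
1800-1809,1800,1809
1810-1819,1810,1819
1820-1829,1820,1829
1830-1839,1830,1839
1840-1849,1840,1849
1850-1859,1850,1859
1860-1869,1860,1869
1870-1879,1870,1879
1880-1889,1880,1889
1890-1899,1890,1899
1900-1909,1900,1909
1910-1919,1910,1919
>1920,1920,2020
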